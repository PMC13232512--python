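"""Recombination-aware detection of highly differentiated genomic windows.

Per-SNP differentiation is measured with the Weir & Cockerham (1984)
variance-component estimator theta = a / (a + b + c) for two populations.
To avoid recombination-rate heterogeneity biasing the outlier threshold
(F_ST distributions have longer tails where recombination is low), every
100 kb window is assigned to one of five quintile bins of the genome-wide
pedigree-map recombination rate, and outlier SNPs are those exceeding the
99th F_ST percentile *within their bin*.

Window-level signal is the binomial upper tail of the outlier-SNP count
given the window's SNP count and the genome-wide outlier proportion p0 —
an enrichment score, not an exact P-value, because neighbouring SNPs are
linked.  Windows with P < 0.05 are "enriched"; adjacent enriched windows
merge into continuous regions.  Enrichment of candidate ("repeated")
regions among enriched windows is tested with a chi-squared statistic whose
null distribution comes from repositioning the enriched windows uniformly
within their chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import BinnedTrack, GenomeLayout, RegionSet, merge_regions, overlap_flags

__all__ = [
    "wc_fst",
    "wc_fst_components",
    "assign_bins",
    "attach_windows_and_bins",
    "binwise_outliers",
    "window_enrichment",
    "WindowScan",
    "pearson_chi2",
    "repeated_overlap_test",
    "OverlapTest",
    "overlap_percentages",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_fst_components(n1, ac1, het1, n2, ac2, het2):
    """Variance components (a, b, c) of the two-population W&C estimator.

    Inputs are arrays (or scalars) of called diploid counts ``n``, alt-allele
    counts ``ac`` (0..2n) and heterozygote individual counts ``het`` per
    population.  Missing genotypes simply reduce ``n``.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    ac1 = np.asarray(ac1, float)
    ac2 = np.asarray(ac2, float)
    het1 = np.asarray(het1, float)
    het2 = np.asarray(het2, float)
    r = 2.0
    p1 = ac1 / (2 * n1)
    p2 = ac2 / (2 * n2)
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (het1 + het2) / (n1 + n2)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_fst(n1, ac1, het1, n2, ac2, het2):
    """Per-locus Weir & Cockerham theta; NaN where a + b + c = 0.

    The estimator may be negative in finite samples; loci monomorphic across
    both populations have no defined value.
    """
    a, b, c = wc_fst_components(n1, ac1, het1, n2, ac2, het2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta if theta.ndim else float(theta)


def add_fst(snp_df: pd.DataFrame) -> pd.DataFrame:
    """Attach a per-SNP ``fst`` column computed from the count columns."""
    out = snp_df.copy()
    out["fst"] = wc_fst(out["n1"], out["ac1"], out["het1"],
                        out["n2"], out["ac2"], out["het2"])
    return out


# ---------------------------------------------------------------------------
# Recombination quintile bins
# ---------------------------------------------------------------------------


def assign_bins(values: np.ndarray, n_bins: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Quintile (by default) bin labels 1..n for an array of rates.

    Edges are linear-interpolation empirical percentiles of the finite
    values; values equal to an edge fall in the lower bin.  Degenerate
    distributions (ties collapsing edges) yield fewer effective bins, with a
    warning.  NaN values get label 0 (unbinned).
    """
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    labels = np.zeros(len(values), dtype=int)
    if not ok.any():
        return labels, np.array([])
    qs = np.linspace(0, 100, n_bins + 1)[1:-1]
    edges = np.percentile(values[ok], qs)
    if len(np.unique(edges)) < len(edges):
        warnings.warn("tied percentile edges: fewer effective recombination bins")
    labels[ok] = np.searchsorted(edges, values[ok], side="left") + 1
    return labels, edges


def attach_windows_and_bins(snp_df: pd.DataFrame, linkage_track: BinnedTrack,
                            window: int = 100_000) -> pd.DataFrame:
    """Assign each SNP its 100 kb window and the window's recombination bin.

    ``linkage_track`` holds the pedigree-map cM/Mb value per ``window`` bp
    window.  Windows without a linkage value are unbinned (label 0) and are
    excluded from the scan downstream.
    """
    if linkage_track.width != window:
        raise ValueError("linkage track width must equal the scan window")
    out = snp_df.copy()
    out["win_start"] = (out["pos"] // window) * window
    labels, _ = assign_bins(linkage_track.df["value"].to_numpy())
    lookup = dict(
        zip(
            zip(linkage_track.df["chrom"], linkage_track.df["start"]),
            labels,
        )
    )
    out["bin"] = [
        lookup.get((c, s), 0) for c, s in zip(out["chrom"], out["win_start"])
    ]
    return out


def binwise_outliers(snp_df: pd.DataFrame, q: float = 0.99,
                     min_bin_snps: int = 100) -> pd.DataFrame:
    """Flag SNPs exceeding the ``q`` F_ST quantile of their recombination bin.

    The threshold is the linear-interpolation empirical quantile; the flag
    uses a strict ``>`` so threshold ties are not outliers.  Unbinned SNPs
    (bin 0) are never flagged.
    """
    out = snp_df.copy()
    out["outlier"] = False
    for b, sub in out[out["bin"] > 0].groupby("bin"):
        vals = sub["fst"].dropna()
        if len(vals) == 0:
            continue
        if len(vals) < min_bin_snps:
            warnings.warn(f"recombination bin {b} has only {len(vals)} SNPs")
        thr = float(np.quantile(vals, q))
        out.loc[sub.index, "outlier"] = sub["fst"] > thr
    return out


# ---------------------------------------------------------------------------
# Window enrichment
# ---------------------------------------------------------------------------


@dataclass
class WindowScan:
    """Result of the binomial window-enrichment scan."""

    windows: pd.DataFrame  # chrom, start, end, n_snps, n_outliers, bin, p, enriched
    p0: float
    alpha: float
    merged: RegionSet
    n_enriched: int
    n_enriched_merged: int
    chi2_bins: tuple[float, float]  # statistic, P for uniformity across bins
    snp_count_corr: tuple[float, float]  # Pearson r, P of P-value vs SNP count

    @property
    def enriched_regions(self) -> RegionSet:
        sub = self.windows.loc[self.windows["enriched"], ["chrom", "start", "end"]]
        if sub.empty:
            return RegionSet.empty()
        return RegionSet(sub.reset_index(drop=True))

    @property
    def background_regions(self) -> RegionSet:
        sub = self.windows.loc[~self.windows["enriched"], ["chrom", "start", "end"]]
        if sub.empty:
            return RegionSet.empty()
        return RegionSet(sub.reset_index(drop=True))


def window_enrichment(snp_df: pd.DataFrame, window: int = 100_000,
                      min_snps: int = 10, alpha: float = 0.05) -> WindowScan:
    """Binomial upper-tail enrichment of outlier SNPs per 100 kb window.

    For a window with n SNPs of which k are outliers, P = P(X >= k) with
    X ~ Binomial(n, p0) and p0 the genome-wide outlier proportion (computed
    after dropping windows with fewer than ``min_snps`` SNPs and unbinned
    windows).  Windows with P < ``alpha`` are enriched; adjacent enriched
    windows (zero gap on the tiling) are merged.  A chi-squared test of
    uniform representation of enriched windows across the recombination bins
    and the Pearson correlation of P with SNP count (density control) are
    attached.
    """
    df = snp_df[snp_df["bin"] > 0]
    grp = df.groupby(["chrom", "win_start"])
    win = grp.agg(
        n_snps=("fst", "size"),
        n_outliers=("outlier", "sum"),
        bin=("bin", "first"),
    ).reset_index()
    win = win[win["n_snps"] >= min_snps].reset_index(drop=True)
    if win.empty:
        raise ValueError("no windows pass the SNP-count filter")
    p0 = float(win["n_outliers"].sum() / win["n_snps"].sum())
    win["p"] = stats.binom.sf(win["n_outliers"] - 1, win["n_snps"], p0)
    win["enriched"] = win["p"] < alpha
    win = win.rename(columns={"win_start": "start"})
    win["end"] = win["start"] + window

    enriched = win.loc[win["enriched"], ["chrom", "start", "end"]]
    merged = (
        merge_regions(RegionSet(enriched.reset_index(drop=True)), max_gap=0)
        if not enriched.empty
        else RegionSet.empty()
    )

    counts = win.loc[win["enriched"], "bin"].value_counts()
    obs = np.array([counts.get(b, 0) for b in range(1, 6)], float)
    if obs.sum() > 0:
        chi2_res = stats.chisquare(obs)
        chi2_bins = (float(chi2_res.statistic), float(chi2_res.pvalue))
    else:
        chi2_bins = (np.nan, np.nan)

    if win["p"].nunique() > 1 and win["n_snps"].nunique() > 1:
        r, p = stats.pearsonr(win["n_snps"], win["p"])
        snp_corr = (float(r), float(p))
    else:
        snp_corr = (np.nan, np.nan)

    cols = ["chrom", "start", "end", "n_snps", "n_outliers", "bin", "p", "enriched"]
    return WindowScan(win[cols], p0, alpha, merged, int(win["enriched"].sum()),
                      merged.n, chi2_bins, snp_corr)


# ---------------------------------------------------------------------------
# Candidate-region overlap test
# ---------------------------------------------------------------------------


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-squared statistic without continuity correction.

    Cells with zero expected count contribute zero (degenerate margins give
    a statistic of 0 rather than an error).
    """
    table = np.asarray(table, float)
    total = table.sum()
    if total == 0:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(exp > 0, (table - exp) ** 2 / exp, 0.0)
    return float(terms.sum())


@dataclass
class OverlapTest:
    """Chi-squared overlap test with a chromosome-preserving permutation null."""

    table: np.ndarray  # rows: enriched / background, cols: overlap / no-overlap
    chi2: float
    null: np.ndarray
    n_perm: int
    n_ge: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_ge = int((self.null >= self.chi2).sum())

    @property
    def p_value(self) -> float:
        return self.n_ge / self.n_perm

    @property
    def p_label(self) -> str:
        if self.n_ge == 0:
            return f"< {1 / self.n_perm:g}"
        return f"{self.p_value:g}"


def _overlap_count(starts, ends, cand_starts, cand_ends) -> int:
    """Count of [start, end) intervals overlapping any candidate interval."""
    n_lt = np.searchsorted(cand_starts, ends, side="left")
    n_le = np.searchsorted(cand_ends, starts, side="right")
    return int((n_lt > n_le).sum())


def repeated_overlap_test(enriched: RegionSet, background: RegionSet,
                          candidates: RegionSet, layout: GenomeLayout,
                          n_perm: int = 500,
                          rng: np.random.Generator | None = None) -> OverlapTest:
    """Do enriched windows overlap candidate regions more than expected?

    Observed statistic: Pearson chi-squared of the 2x2 table of
    (enriched / background) x (overlaps a candidate / does not).  Null: at
    each of ``n_perm`` iterations the enriched windows are repositioned
    uniformly within their own chromosome, preserving window size (windows
    never extend past the chromosome end; permuted windows may overlap each
    other), and the statistic is recomputed with the background fixed.  The
    empirical P is the fraction of permuted statistics >= the observed one,
    reported as "< 1/n_perm" when zero.
    """
    if candidates.n == 0:
        raise ValueError("candidate region set is empty")
    rng = rng if rng is not None else np.random.default_rng()

    cand_sorted = {
        chrom: (np.sort(sub["start"].to_numpy(np.int64)),
                np.sort(sub["end"].to_numpy(np.int64)))
        for chrom, sub in candidates.df.groupby("chrom", sort=False)
    }

    def count_overlaps(df: pd.DataFrame) -> int:
        total = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in cand_sorted:
                continue
            cs, ce = cand_sorted[chrom]
            total += _overlap_count(sub["start"].to_numpy(np.int64),
                                    sub["end"].to_numpy(np.int64), cs, ce)
        return total

    e_ov = count_overlaps(enriched.df)
    b_ov = count_overlaps(background.df)
    table = np.array([[e_ov, enriched.n - e_ov], [b_ov, background.n - b_ov]], float)
    observed = pearson_chi2(table)

    chroms = enriched.df["chrom"].to_numpy(object)
    sizes = (enriched.df["end"] - enriched.df["start"]).to_numpy(np.int64)
    max_start = np.array([layout[c] for c in chroms], np.int64) - sizes
    if (max_start < 0).any():
        raise ValueError("enriched window longer than its chromosome")

    null = np.empty(n_perm)
    for i in range(n_perm):
        starts = rng.integers(0, max_start + 1)
        perm = pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + sizes})
        pe = count_overlaps(perm)
        t = np.array([[pe, enriched.n - pe], [b_ov, background.n - b_ov]], float)
        null[i] = pearson_chi2(t)
    return OverlapTest(table=table, chi2=observed, null=null, n_perm=n_perm)


def overlap_percentages(enriched: RegionSet, candidates: RegionSet) -> dict:
    """Two-way overlap tallies between enriched windows and candidate regions.

    Returns the percentage of enriched windows overlapping at least one
    candidate region and the percentage of candidate regions containing at
    least one enriched window, both to 2 decimal places.
    """
    e_flags = overlap_flags(enriched, candidates) if enriched.n and candidates.n else np.zeros(0, bool)
    c_flags = overlap_flags(candidates, enriched) if enriched.n and candidates.n else np.zeros(0, bool)
    return {
        "n_enriched": enriched.n,
        "n_enriched_overlapping": int(e_flags.sum()),
        "pct_enriched_overlapping": round(100.0 * e_flags.sum() / enriched.n, 2)
        if enriched.n
        else 0.0,
        "n_candidates": candidates.n,
        "n_candidates_hit": int(c_flags.sum()),
        "pct_candidates_hit": round(100.0 * c_flags.sum() / candidates.n, 2)
        if candidates.n
        else 0.0,
    }
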