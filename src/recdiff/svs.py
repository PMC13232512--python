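"""Structural-variant statistics: outliers, LD suppression, spot enrichment.

The SV layer treats each deletion, insertion or inversion as a biallelic
locus genotyped across both populations, so per-SV differentiation uses the
same Weir & Cockerham estimator as SNPs, with outliers above the 99th
percentile of the SV F_ST distribution.  Outlier SVs are tested for
co-location with the SNP-based enriched windows (two-sided Fisher exact
test, overall and stratified by size at 1 kb), with SV density per window
as a control.

LD suppression is probed with one SNP pair per SV: the nearest SNP strictly
left of the SV's reference span and the nearest strictly right of it, each
within 5 kb of its breakend.  The key predictor is

    proportion covered = |SV length| / (pos_SNP2 - pos_SNP1),

and r² between the flanking SNPs is modelled with a linear mixed model
(fixed: scaled inverse frequency-weighted distance, scaled proportion
covered, SV type; random: chromosome intercept) fitted by REML.  Marginal
means per SV type are fixed-effect predictions at covariate means, and type
contrasts come from the fixed-effect covariance.

Finally, SV enrichment in recombination hot/coldspot categories is tested
by shuffling the regions uniformly along their chromosome (lengths
preserved) and counting overlapping SVs, 10,000 times by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .intervals import GenomeLayout, RegionSet, sv_ref_span
from .diffscan import wc_fst

__all__ = [
    "catalogue_summary",
    "sv_fst_outliers",
    "sv_spans",
    "sv_overlap_fisher",
    "sv_density_control",
    "flanking_pairs",
    "build_ld_features",
    "fit_ld_model",
    "LdModelResult",
    "spot_enrichment",
    "SpotEnrichment",
]

SV_TYPES = ("DEL", "INS", "INV")


def catalogue_summary(sv_df: pd.DataFrame) -> dict:
    """Per-type counts and length statistics; counts sum to the total."""
    out: dict = {"total": int(len(sv_df)), "by_type": {}}
    for t in SV_TYPES:
        sub = sv_df[sv_df["svtype"] == t]
        out["by_type"][t] = {
            "count": int(len(sub)),
            "mean_length": float(sub["length"].mean()) if len(sub) else 0.0,
            "min_length": int(sub["length"].min()) if len(sub) else 0,
            "max_length": int(sub["length"].max()) if len(sub) else 0,
        }
    unknown = sv_df[~sv_df["svtype"].isin(SV_TYPES)]
    if len(unknown):
        warnings.warn(f"{len(unknown)} records with unknown SVTYPE rejected")
        out["total"] = int(len(sv_df) - len(unknown))
    return out


def add_sv_fst(sv_df: pd.DataFrame) -> pd.DataFrame:
    """Per-SV Weir & Cockerham F_ST from genotype count columns."""
    out = sv_df.copy()
    out["fst"] = wc_fst(out["n1"], out["ac1"], out["het1"],
                        out["n2"], out["ac2"], out["het2"])
    return out


def sv_fst_outliers(sv_df: pd.DataFrame, q: float = 0.99) -> pd.DataFrame:
    """Flag SVs strictly exceeding the ``q`` quantile of the SV F_ST values."""
    out = sv_df.copy()
    vals = out["fst"].dropna()
    thr = float(np.quantile(vals, q)) if len(vals) else np.inf
    out["outlier"] = out["fst"] > thr
    return out


def sv_spans(sv_df: pd.DataFrame) -> RegionSet:
    """Reference spans of SVs (DEL/INV: [pos, pos+len); INS: 1 bp anchor)."""
    spans = [
        sv_ref_span(t, int(p), int(l))
        for t, p, l in zip(sv_df["svtype"], sv_df["pos"], sv_df["length"])
    ]
    return RegionSet(
        pd.DataFrame(
            {"chrom": sv_df["chrom"].to_numpy(),
             "start": [s for s, _ in spans],
             "end": [e for _, e in spans]}
        )
    )


def _span_overlap_flags(sv_df: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    """Per-SV overlap flags against ``regions``, in sv_df row order."""
    spans_df = pd.DataFrame(
        {
            "chrom": sv_df["chrom"].to_numpy(),
            "start": [sv_ref_span(t, int(p), int(l))[0]
                      for t, p, l in zip(sv_df["svtype"], sv_df["pos"], sv_df["length"])],
            "end": [sv_ref_span(t, int(p), int(l))[1]
                    for t, p, l in zip(sv_df["svtype"], sv_df["pos"], sv_df["length"])],
        }
    )
    out = np.zeros(len(spans_df), dtype=bool)
    for chrom, sub in regions.df.groupby("chrom", sort=False):
        sel = spans_df["chrom"] == chrom
        if not sel.any():
            continue
        rs = np.sort(sub["start"].to_numpy(np.int64))
        re = np.sort(sub["end"].to_numpy(np.int64))
        s = spans_df.loc[sel, "start"].to_numpy(np.int64)
        e = spans_df.loc[sel, "end"].to_numpy(np.int64)
        out[np.flatnonzero(sel.to_numpy())] = (
            np.searchsorted(rs, e, side="left") > np.searchsorted(re, s, side="right")
        )
    return out


def sv_overlap_fisher(sv_df: pd.DataFrame, enriched: RegionSet,
                      size_threshold: int | None = None,
                      size_class: str | None = None) -> dict:
    """Two-sided Fisher exact test of outlier SVs falling in enriched windows.

    ``sv_df`` needs an ``outlier`` flag column.  With ``size_class`` 'large'
    or 'small' the test is restricted to SVs >= / < ``size_threshold``
    (default 1 kb).  A zero margin leaves the odds ratio undefined; the
    report then carries a note (no Haldane correction is applied to the
    statistic itself).
    """
    df = sv_df
    if size_class is not None:
        thr = size_threshold if size_threshold is not None else 1_000
        sel = df["length"] >= thr if size_class == "large" else df["length"] < thr
        df = df[sel]
    ov = _span_overlap_flags(df, enriched) if enriched.n else np.zeros(len(df), bool)
    out_flag = df["outlier"].to_numpy(bool)
    table = np.array(
        [
            [int((out_flag & ov).sum()), int((out_flag & ~ov).sum())],
            [int((~out_flag & ov).sum()), int((~out_flag & ~ov).sum())],
        ]
    )
    res = stats.fisher_exact(table, alternative="two-sided")
    report = {
        "table": table.tolist(),
        "odds_ratio": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(len(df)),
    }
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any() or (table == 0).any():
        if not np.isfinite(res.statistic) or res.statistic == 0 or (table == 0).any():
            report["note"] = ("zero cell or margin: conditional odds ratio "
                              "unstable; a Haldane-corrected ratio would be "
                              "needed for a finite point estimate")
    return report


def sv_density_control(sv_df: pd.DataFrame, windows: pd.DataFrame,
                       window: int = 100_000) -> dict:
    """Spearman correlation of per-window SV density with -log10 scan P.

    Density is the proportion of window bases occupied by SVs, with
    deletions and insertions contributing 1 bp each and inversions their
    length (clipped to the window).  ``windows`` is the scan table with
    chrom/start/p columns.
    """
    occ: dict[tuple[str, int], float] = {}
    for t, chrom, p, l in zip(sv_df["svtype"], sv_df["chrom"], sv_df["pos"],
                              sv_df["length"]):
        if t in ("DEL", "INS"):
            s, e = int(p), int(p) + 1
        else:
            s, e = int(p), int(p) + int(l)
        for ws in range((s // window) * window, e, window):
            key = (chrom, ws)
            occ[key] = occ.get(key, 0.0) + (min(e, ws + window) - max(s, ws))
    dens = np.array(
        [occ.get((c, int(s)), 0.0) / (e - s)
         for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])]
    )
    logp = -np.log10(windows["p"].to_numpy(float))
    if np.std(dens) == 0 or np.std(logp) == 0:
        return {"rho": None, "p": None, "note": "degenerate (constant) input",
                "density": dens}
    rho, p = stats.spearmanr(dens, logp)
    return {"rho": float(rho), "p": float(p), "density": dens}


# ---------------------------------------------------------------------------
# LD features around SVs
# ---------------------------------------------------------------------------


def flanking_pairs(sv_df: pd.DataFrame, snp_pos: pd.DataFrame,
                   flank: int = 5_000) -> pd.DataFrame:
    """One flanking SNP pair per SV, or no row if either flank is missing.

    The left SNP is the nearest strictly before the SV's reference span
    start and within ``flank`` bp of it; the right SNP the nearest strictly
    after the span end and within ``flank`` bp.  Output keeps the SV row
    index in ``sv_index``.
    """
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy(np.int64))
        for chrom, sub in snp_pos.groupby("chrom", sort=False)
    }
    rows = []
    for idx, row in sv_df.iterrows():
        pos = pos_by_chrom.get(row["chrom"])
        if pos is None or len(pos) == 0:
            continue
        s, e = sv_ref_span(row["svtype"], int(row["pos"]), int(row["length"]))
        i_left = np.searchsorted(pos, s, side="left") - 1
        i_right = np.searchsorted(pos, e, side="right")
        if i_left < 0 or i_right >= len(pos):
            continue
        pa, pb = int(pos[i_left]), int(pos[i_right])
        if s - pa > flank or pb - e > flank:
            continue
        rows.append((idx, row["chrom"], pa, pb, row["svtype"], int(row["length"])))
    return pd.DataFrame(
        rows, columns=["sv_index", "chrom", "posA", "posB", "svtype", "length"]
    )


def build_ld_features(sv_df: pd.DataFrame, snps: pd.DataFrame,
                      ld_records: pd.DataFrame, flank: int = 5_000,
                      max_pair_span: int = 35_000) -> pd.DataFrame:
    """LD model features: one flanking SNP pair with r² per retained SV.

    ``snps`` needs chrom/pos and, when available, a ``maf`` column used by
    the inverse frequency-weighted distance
    ``1 / ((posB - posA) * maf_A * maf_B)`` (a declared stand-in for an
    undefined literature weighting; SNPs without a MAF get 0.5).  SVs
    lacking either flank, an r² record for the pair, or whose pair spans
    more than ``max_pair_span`` bp are dropped; the drop count is in
    ``df.attrs['n_dropped']``.
    """
    pairs = flanking_pairs(sv_df, snps, flank=flank)
    ld_key = {
        (c, int(a), int(b)): float(r)
        for c, a, b, r in zip(ld_records["chrom"], ld_records["posA"],
                              ld_records["posB"], ld_records["r2"])
    }
    maf_key: Mapping = {}
    if "maf" in snps.columns:
        maf_key = dict(zip(zip(snps["chrom"], snps["pos"]), snps["maf"]))
    rows = []
    n_dropped = len(sv_df) - len(pairs)
    for row in pairs.itertuples(index=False):
        span = row.posB - row.posA
        if span > max_pair_span:
            n_dropped += 1
            continue
        r2 = ld_key.get((row.chrom, row.posA, row.posB))
        if r2 is None:
            n_dropped += 1
            continue
        maf_a = float(maf_key.get((row.chrom, row.posA), 0.5))
        maf_b = float(maf_key.get((row.chrom, row.posB), 0.5))
        rows.append(
            (row.sv_index, row.chrom, row.posA, row.posB, row.svtype,
             row.length, r2, row.length / span,
             1.0 / (span * max(maf_a, 1e-12) * max(maf_b, 1e-12)))
        )
    out = pd.DataFrame(
        rows,
        columns=["sv_index", "chrom", "posA", "posB", "svtype", "length", "r2",
                 "prop_covered", "inv_freq_dist"],
    )
    out.attrs["n_dropped"] = int(n_dropped)
    # a SNP pair spanning two SVs stays attached to both; flag such pairs
    dup = out.duplicated(subset=["chrom", "posA", "posB"], keep=False)
    out["shared_pair"] = dup.to_numpy()
    return out


@dataclass
class LdModelResult:
    fixed: pd.Series
    fixed_bse: pd.Series
    chrom_var: float
    marginal_means: dict
    contrasts: dict
    method: str  # 'mixed' or 'ols'

    def to_dict(self) -> dict:
        return {
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "fixed_bse": {k: float(v) for k, v in self.fixed_bse.items()},
            "chrom_var": float(self.chrom_var),
            "marginal_means": self.marginal_means,
            "contrasts": self.contrasts,
            "method": self.method,
        }


def _scale(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return (x - np.mean(x)) / sd if sd > 0 else x - np.mean(x)


def fit_ld_model(features: pd.DataFrame, reml: bool = True) -> LdModelResult:
    """Mixed model of r² around SVs with a chromosome random intercept.

    r² ~ scaled(inverse frequency-weighted distance) + scaled(proportion
    covered) + SV type, random intercept per chromosome (REML).  With a
    single chromosome the model falls back to plain OLS with a warning.
    Marginal means per SV type are fixed-effect predictions at covariate
    means (the random intercept has mean zero); pairwise type contrasts use
    the fixed-effect covariance with normal-theory P values.
    """
    if len(features) < 10:
        raise ValueError("need at least 10 LD features")
    df = features.copy()
    df["dist_s"] = _scale(df["inv_freq_dist"].to_numpy(float))
    df["prop_s"] = _scale(df["prop_covered"].to_numpy(float))
    df["svtype"] = pd.Categorical(df["svtype"],
                                  categories=[t for t in SV_TYPES
                                              if t in set(df["svtype"])])
    formula = "r2 ~ dist_s + prop_s + C(svtype)"
    n_chrom = df["chrom"].nunique()
    if n_chrom < 2:
        warnings.warn("single chromosome: falling back to fixed-intercept OLS")
        fit = smf.ols(formula, data=df).fit()
        params, bse, cov = fit.params, fit.bse, fit.cov_params()
        chrom_var, method = 0.0, "ols"
    else:
        with warnings.catch_warnings():
            # boundary fits (random variance ~ 0) emit harmless warnings
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["chrom"])
            fit = model.fit(reml=reml, method="lbfgs")
            params = fit.fe_params
            cov = fit.cov_params().loc[params.index, params.index]
            bse = fit.bse_fe.loc[params.index]
        chrom_var, method = float(fit.cov_re.iloc[0, 0]), "mixed"

    types = list(df["svtype"].cat.categories)
    design = {}
    for t in types:
        x = pd.Series(0.0, index=params.index)
        x["Intercept"] = 1.0
        key = f"C(svtype)[T.{t}]"
        if key in x.index:
            x[key] = 1.0
        design[t] = x
    mm = {t: float(design[t] @ params) for t in types}
    contrasts = {}
    for i, t1 in enumerate(types):
        for t2 in types[i + 1:]:
            L = design[t1] - design[t2]
            est = float(L @ params)
            se = float(np.sqrt(L @ cov.values @ L))
            z = est / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            contrasts[f"{t1}_vs_{t2}"] = {"estimate": est, "se": se, "z": z,
                                          "p": float(p)}
    return LdModelResult(params, bse, chrom_var, mm, contrasts, method)


# ---------------------------------------------------------------------------
# Hot/coldspot enrichment
# ---------------------------------------------------------------------------


@dataclass
class SpotEnrichment:
    observed: int
    expected: float
    ratio: float
    p: float
    n_shuffles: int

    def to_dict(self) -> dict:
        return {"observed": self.observed, "expected": self.expected,
                "ratio": self.ratio, "p": self.p, "n_shuffles": self.n_shuffles}


def spot_enrichment(sv_df: pd.DataFrame, regions: RegionSet,
                    layout: GenomeLayout, n_shuffles: int = 10_000,
                    rng: np.random.Generator | None = None) -> SpotEnrichment:
    """Permutation enrichment of SVs in a region category (hot/coldspots).

    Observed: number of SVs whose reference span overlaps any region.  Null:
    regions repositioned uniformly within their chromosome (lengths
    preserved), ``n_shuffles`` times; the one-sided P is the proportion of
    shuffles with at least as many overlapping SVs, and the enrichment ratio
    is observed over the mean shuffled count.
    """
    rng = rng if rng is not None else np.random.default_rng()
    spans = pd.DataFrame(
        {
            "chrom": sv_df["chrom"].to_numpy(),
            "start": [sv_ref_span(t, int(p), int(l))[0]
                      for t, p, l in zip(sv_df["svtype"], sv_df["pos"], sv_df["length"])],
            "end": [sv_ref_span(t, int(p), int(l))[1]
                    for t, p, l in zip(sv_df["svtype"], sv_df["pos"], sv_df["length"])],
        }
    )
    sv_by_chrom = {
        chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for chrom, sub in spans.groupby("chrom", sort=False)
    }
    obs = 0
    null = np.zeros(n_shuffles, dtype=np.int64)
    for chrom, sub in regions.df.groupby("chrom", sort=False):
        if chrom not in sv_by_chrom:
            continue
        sv_s, sv_e = sv_by_chrom[chrom]
        sizes = (sub["end"] - sub["start"]).to_numpy(np.int64)
        if (sizes > layout[chrom]).any():
            raise ValueError(f"region longer than chromosome {chrom}")
        starts = sub["start"].to_numpy(np.int64)
        hit = np.zeros(len(sv_s), dtype=bool)
        for s, size in zip(starts, sizes):
            hit |= (sv_s < s + size) & (sv_e > s)
        obs += int(hit.sum())
        max_start = layout[chrom] - sizes
        hit_null = np.zeros((n_shuffles, len(sv_s)), dtype=bool)
        for j, size in enumerate(sizes):
            rs = rng.integers(0, max_start[j] + 1, size=n_shuffles)
            hit_null |= (sv_s[None, :] < (rs + size)[:, None]) & (
                sv_e[None, :] > rs[:, None]
            )
        null += hit_null.sum(axis=1)
    expected = float(null.mean()) if n_shuffles else float("nan")
    ratio = obs / expected if expected > 0 else float("inf") if obs else 1.0
    p = float((null >= obs).mean()) if n_shuffles else float("nan")
    return SpotEnrichment(obs, expected, float(ratio), p, n_shuffles)
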