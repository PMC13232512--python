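"""Windowed nucleotide diversity and recombination-differentiation models.

Three linked analyses:

* missing-data-aware windowed pi per population: per variant site the
  pairwise-difference term is ``2 * c_alt * (n - c_alt) / (n * (n - 1))``
  over the ``n`` called alleles, and the window value divides the summed
  terms by the full window length, treating unobserved sites as monomorphic;
* an OLS model of log windowed F_ST on pedigree recombination rate, pi and
  their interaction, fitted separately per population — the interaction
  captures the stronger pi-F_ST coupling in low-recombination regions;
* residuals of log(LD-based rate) regressed on pedigree cM/Mb per window:
  negative residuals mark windows with more LD (less effective
  recombination) than the meiotic map predicts.  Residuals are correlated
  with pi and F_ST, and compared across window categories (background,
  outlier, outlier overlapping a repeated region) with Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .intervals import BinnedTrack, GenomeLayout
from .diffscan import wc_fst_components

__all__ = [
    "windowed_pi",
    "pi_population_test",
    "windowed_fst",
    "fst_pi_recomb_model",
    "ld_map_residuals",
    "residual_tests",
]


def windowed_pi(snp_df: pd.DataFrame, pop: int, window: int,
                layout: GenomeLayout) -> BinnedTrack:
    """Per-window nucleotide diversity for population ``pop`` (1 or 2).

    Uses the allele counts of variant sites only; all other positions in the
    window are treated as monomorphic, so the denominator is the full window
    length (the final window of a chromosome may be short and uses its true
    length).  Sites with fewer than two called alleles contribute nothing.
    """
    n_col, ac_col = f"n{pop}", f"ac{pop}"
    n_alleles = 2 * snp_df[n_col].to_numpy(float)
    ac = snp_df[ac_col].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 2.0 * ac * (n_alleles - ac) / (n_alleles * (n_alleles - 1))
    term = np.where(n_alleles >= 2, term, 0.0)

    win_start = (snp_df["pos"].to_numpy(np.int64) // window) * window
    sums: dict[tuple[str, int], float] = {}
    for chrom, ws, t in zip(snp_df["chrom"], win_start, term):
        sums[(chrom, int(ws))] = sums.get((chrom, int(ws)), 0.0) + float(t)

    rows = []
    for chrom in layout.chroms:
        span = layout[chrom]
        for start in range(0, span, window):
            end = min(start + window, span)
            rows.append((chrom, start, end, sums.get((chrom, start), 0.0) / (end - start)))
    return BinnedTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
                       window)


def pi_population_test(track_a: BinnedTrack, track_b: BinnedTrack) -> tuple[float, float]:
    """Welch two-sample t-test of mean window pi between populations."""
    a = track_a.df["value"].dropna().to_numpy()
    b = track_b.df["value"].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two windows per population")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def windowed_fst(snp_df: pd.DataFrame, window: int,
                 layout: GenomeLayout) -> BinnedTrack:
    """Windowed Weir & Cockerham F_ST as the ratio of summed components.

    Per window, F_ST = sum(a) / sum(a + b + c) over its SNPs (the standard
    multi-locus combination, less noisy than averaging per-SNP ratios);
    windows without SNPs are NaN.
    """
    a, b, c = wc_fst_components(snp_df["n1"], snp_df["ac1"], snp_df["het1"],
                                snp_df["n2"], snp_df["ac2"], snp_df["het2"])
    win_start = (snp_df["pos"].to_numpy(np.int64) // window) * window
    num: dict[tuple[str, int], float] = {}
    den: dict[tuple[str, int], float] = {}
    for chrom, ws, ai, di in zip(snp_df["chrom"], win_start, a, a + b + c):
        if not np.isfinite(di):
            continue
        key = (chrom, int(ws))
        num[key] = num.get(key, 0.0) + float(ai)
        den[key] = den.get(key, 0.0) + float(di)
    rows = []
    for chrom in layout.chroms:
        span = layout[chrom]
        for start in range(0, span, window):
            end = min(start + window, span)
            key = (chrom, start)
            val = num[key] / den[key] if den.get(key) else np.nan
            rows.append((chrom, start, end, val))
    return BinnedTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
                       window)


@dataclass
class OlsReport:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    adj_r2: float
    n: int
    n_dropped: int

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "adj_r2": float(self.adj_r2),
            "n": int(self.n),
            "n_dropped": int(self.n_dropped),
        }


def fst_pi_recomb_model(windows: pd.DataFrame) -> OlsReport:
    """OLS of log F_ST on recombination rate, pi and their interaction.

    ``windows`` needs columns fst, rec (cM/Mb) and pi.  Windows with missing
    values or non-positive F_ST are dropped before the log (their count is
    reported).  Raises on a rank-deficient design (e.g. rec and pi
    perfectly collinear).
    """
    df = windows[["fst", "rec", "pi"]].dropna()
    n_dropped = int(len(windows) - len(df) + (df["fst"] <= 0).sum())
    df = df[df["fst"] > 0]
    X = pd.DataFrame(
        {
            "const": 1.0,
            "rec": df["rec"],
            "pi": df["pi"],
            "rec:pi": df["rec"] * df["pi"],
        }
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(np.log(df["fst"]), X).fit()
    return OlsReport(fit.params, fit.bse, fit.pvalues, float(fit.rsquared_adj),
                     int(fit.nobs), n_dropped)


def ld_map_residuals(rho_track: BinnedTrack, linkage_track: BinnedTrack,
                     rate_floor_factor: float = 1e-3) -> pd.DataFrame:
    """Residuals of log(LD-based rate) regressed on pedigree cM/Mb per window.

    Windows missing either value are dropped; zero LD-based rates are
    floored at the smallest positive rate times ``rate_floor_factor`` before
    the natural log.  If the LD rate is an exact monotone function of cM/Mb
    the residuals vanish and downstream correlations are undefined — callers
    get a flag column ``degenerate`` on the frame attributes.
    """
    if not rho_track.same_grid(linkage_track):
        raise ValueError("rho and linkage tracks must share a grid")
    df = rho_track.df[["chrom", "start", "end"]].copy()
    rho = rho_track.df["value"].to_numpy(float)
    cmmb = linkage_track.df["value"].to_numpy(float)
    ok = np.isfinite(rho) & np.isfinite(cmmb)
    df, rho, cmmb = df.loc[ok].reset_index(drop=True), rho[ok], cmmb[ok]
    pos = rho[rho > 0]
    floor = pos.min() * rate_floor_factor if len(pos) else 1.0
    log_rho = np.log(np.maximum(rho, floor))
    X = sm.add_constant(cmmb)
    fit = sm.OLS(log_rho, X).fit()
    df["log_rho"] = log_rho
    df["cmmb"] = cmmb
    df["residual"] = fit.resid
    df.attrs["slope"] = float(fit.params[1])
    df.attrs["degenerate"] = bool(np.allclose(fit.resid, 0.0))
    return df


def residual_tests(resid_df: pd.DataFrame, pi1: BinnedTrack, pi2: BinnedTrack,
                   fst: BinnedTrack, categories: pd.Series) -> dict:
    """Correlations of map residuals with pi/F_ST plus category contrasts.

    ``categories`` is aligned with ``resid_df`` and takes values
    'background', 'outlier', 'outlier_repeated'.  Returns Pearson
    correlations of residuals with pi (each population), raw F_ST and
    log F_ST, and Welch t-tests of residual means between each outlier
    category and the background and between the two outlier categories
    (skipped when a category has fewer than two windows).
    """
    if resid_df.attrs.get("degenerate"):
        return {"degenerate": True}

    def values_on(track: BinnedTrack) -> np.ndarray:
        lookup = dict(zip(zip(track.df["chrom"], track.df["start"]),
                          track.df["value"]))
        return np.array([lookup.get((c, s), np.nan)
                         for c, s in zip(resid_df["chrom"], resid_df["start"])])

    res = resid_df["residual"].to_numpy()
    out: dict = {"degenerate": False, "correlations": {}, "contrasts": {}}
    fst_vals = values_on(fst)
    with np.errstate(invalid="ignore", divide="ignore"):
        log_fst = np.where(fst_vals > 0, np.log(fst_vals), np.nan)
    for name, vals in (("pi_pop1", values_on(pi1)), ("pi_pop2", values_on(pi2)),
                       ("fst", fst_vals), ("log_fst", log_fst)):
        ok = np.isfinite(vals) & np.isfinite(res)
        if ok.sum() >= 3 and np.std(vals[ok]) > 0:
            r, p = stats.pearsonr(res[ok], vals[ok])
            out["correlations"][name] = {"r": float(r), "p": float(p),
                                         "n": int(ok.sum())}
    cats = categories.to_numpy()
    groups = {
        "background": res[cats == "background"],
        "outlier": res[cats == "outlier"],
        "outlier_repeated": res[cats == "outlier_repeated"],
    }
    out["category_means"] = {
        k: (float(np.mean(v)) if len(v) else None) for k, v in groups.items()
    }
    pairs = [("outlier_repeated", "background"), ("outlier", "background"),
             ("outlier_repeated", "outlier")]
    for g1, g2 in pairs:
        a, b = groups[g1], groups[g2]
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            out["contrasts"][f"{g1}_vs_{g2}"] = {"t": float(t), "p": float(p),
                                                 "n1": len(a), "n2": len(b)}
    return out
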