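"""Recombination-landscape divergence between two populations.

The broad-scale statistic is the population recombination divergence index
(PRDI): recombination maps from replicate subsets of each population are
averaged into 2 kb bins, Spearman-correlated pairwise inside 5 Mb windows,
and the empirical divergence ``me`` = min(median within-population rho) -
median(between-population rho) is contrasted with the same quantity ``ms``
computed on maps inferred from neutral data sharing one landscape:
PRDI = me - ms.  Because the statistic is rank-based it is invariant to any
strictly monotone transform of the rates.

Fine-scale divergence is localised with Δr: for each complete 100 kb window
of 50 adjacent 2 kb bins, the Manhattan distance between two binned maps is
scaled by the bin count and log transformed,
Δr = ln(mean |a_b - b_b| + eps).  Windows whose median between-population Δr
exceeds the genome-wide mean of within-population Δr by three SDs are
flagged as divergence outliers.

Hotspots and coldspots are bins whose log rate deviates from the local
(+/- 20 kb) background mean by more than three local SDs, merged with a 1 kb
maximum gap; hotspots longer than 5 kb are discarded as artefact-prone.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import BinnedTrack, RegionSet, merge_regions, overlap_flags

__all__ = [
    "window_spearman",
    "compute_me",
    "compute_prdi",
    "prdi_profile",
    "PrdiResult",
    "delta_r",
    "delta_r_medians",
    "delta_r_outliers",
    "call_spots",
    "sharing_summary",
]

WITHIN_KINDS = ("within_pop1", "within_pop2")


# ---------------------------------------------------------------------------
# Windowed Spearman panel and PRDI
# ---------------------------------------------------------------------------


def _pair_kind(pop_a: str, pop_b: str, pops: list[str]) -> str:
    if pop_a == pop_b:
        return "within_pop1" if pop_a == pops[0] else "within_pop2"
    return "between"


def window_spearman(tracks: dict[tuple[str, int], BinnedTrack],
                    window: int = 5_000_000,
                    min_bins: int = 10) -> pd.DataFrame:
    """Pairwise Spearman correlations of binned rates in genomic windows.

    ``tracks`` maps (population, replicate) to tracks on a shared bin grid.
    Every replicate pair is correlated inside each ``window`` bp window and
    classified as within-population or between-population.  Bins missing in
    either member of a pair are dropped pairwise; windows with fewer than
    ``min_bins`` paired bins give NaN for that pair.
    """
    keys = list(tracks)
    pops = list(dict.fromkeys(pop for pop, _ in keys))
    if len(pops) != 2:
        raise ValueError("expected tracks from exactly two populations")
    ref = tracks[keys[0]]
    width = ref.width
    if window % width:
        raise ValueError("window must be a multiple of the bin width")
    for k in keys[1:]:
        if not tracks[k].same_grid(ref):
            raise ValueError("tracks do not share a bin grid")

    grid = ref.df[["chrom", "start"]]
    values = np.column_stack([tracks[k].df["value"].to_numpy() for k in keys])
    win_id = grid["start"].to_numpy() // window

    rows = []
    for (chrom, wid), idx in grid.groupby([grid["chrom"], win_id]).groups.items():
        block = values[np.asarray(idx)]
        for ia, ib in itertools.combinations(range(len(keys)), 2):
            x, y = block[:, ia], block[:, ib]
            ok = np.isfinite(x) & np.isfinite(y)
            rho = np.nan
            if ok.sum() >= min_bins:
                rho = stats.spearmanr(x[ok], y[ok]).statistic
            rows.append(
                (chrom, int(wid) * window,
                 _pair_kind(keys[ia][0], keys[ib][0], pops),
                 f"{keys[ia][0]}:{keys[ia][1]}", f"{keys[ib][0]}:{keys[ib][1]}",
                 rho, int(ok.sum()))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "kind", "rep_a", "rep_b", "rho", "n_bins"]
    )


def compute_me(panel: pd.DataFrame) -> float:
    """Divergence statistic of a correlation panel.

    me = min(median within-pop1 rho, median within-pop2 rho)
         - median(between rho), with medians pooled over all windows and
    replicate pairs (NaN correlations dropped).
    """
    med = {}
    for kind in (*WITHIN_KINDS, "between"):
        vals = panel.loc[panel["kind"] == kind, "rho"].dropna()
        if vals.empty:
            raise ValueError(f"no correlations of kind {kind!r}")
        med[kind] = float(vals.median())
    return min(med["within_pop1"], med["within_pop2"]) - med["between"]


@dataclass(frozen=True)
class PrdiResult:
    me: float
    ms: float

    @property
    def prdi(self) -> float:
        return self.me - self.ms


def compute_prdi(me: float, ms: float) -> PrdiResult:
    """PRDI = empirical divergence minus neutral (simulated) divergence."""
    return PrdiResult(me=me, ms=ms)


def prdi_profile(empirical: pd.DataFrame, neutral: pd.DataFrame) -> pd.DataFrame:
    """Per-window PRDI: the me - ms contrast applied window by window.

    Windows are matched on (chrom, start); windows absent from either panel
    are dropped.
    """
    def per_window(panel):
        out = {}
        for (chrom, start), sub in panel.groupby(["chrom", "start"]):
            med = {}
            for kind in (*WITHIN_KINDS, "between"):
                vals = sub.loc[sub["kind"] == kind, "rho"].dropna()
                if vals.empty:
                    med = None
                    break
                med[kind] = float(vals.median())
            if med is not None:
                out[(chrom, start)] = (
                    min(med["within_pop1"], med["within_pop2"]) - med["between"]
                )
        return out

    emp = per_window(empirical)
    neu = per_window(neutral)
    rows = []
    for key in sorted(emp):
        if key in neu:
            chrom, start = key
            rows.append((chrom, start, emp[key] - neu[key], emp[key], neu[key]))
    return pd.DataFrame(rows, columns=["chrom", "start", "prdi", "me", "ms"])


# ---------------------------------------------------------------------------
# Δr
# ---------------------------------------------------------------------------


def delta_r(track_a: BinnedTrack, track_b: BinnedTrack,
            window: int = 100_000, eps: float = 1e-12) -> pd.DataFrame:
    """Per-window log-scaled Manhattan distance between two binned maps.

    Δr = ln( (1/k) Σ |a_b - b_b| + eps ) over the k bins of each complete
    ``window`` bp window; windows with any missing bin, or short at the
    chromosome end, are dropped.
    """
    if not track_a.same_grid(track_b):
        raise ValueError("tracks do not share a bin grid")
    width = track_a.width
    if window % width:
        raise ValueError("window must be a multiple of the bin width")
    k = window // width
    rows = []
    for chrom, sub in track_a.df.groupby("chrom", sort=False):
        a = sub["value"].to_numpy()
        b = track_b.df.loc[sub.index, "value"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        n_win = len(a) // k
        for i in range(n_win):
            sl = slice(i * k, (i + 1) * k)
            aa, bb = a[sl], b[sl]
            if ends[sl][-1] - starts[sl][0] != window:
                continue
            if not (np.isfinite(aa).all() and np.isfinite(bb).all()):
                continue
            rows.append((chrom, int(starts[sl][0]),
                         math.log(np.abs(aa - bb).mean() + eps)))
    return pd.DataFrame(rows, columns=["chrom", "start", "dr"])


def delta_r_medians(tracks: dict[tuple[str, int], BinnedTrack],
                    window: int = 100_000, eps: float = 1e-12) -> pd.DataFrame:
    """Median within- and between-population Δr per 100 kb window.

    All replicate pairs are evaluated; a window enters the output only if it
    is complete in every pair (so medians compare like with like).
    """
    keys = list(tracks)
    pops = list(dict.fromkeys(pop for pop, _ in keys))
    frames = []
    for ia, ib in itertools.combinations(range(len(keys)), 2):
        df = delta_r(tracks[keys[ia]], tracks[keys[ib]], window, eps)
        df["kind"] = ("within" if keys[ia][0] == keys[ib][0] else "between")
        frames.append(df)
    allpairs = pd.concat(frames, ignore_index=True)
    n_pairs = len(keys) * (len(keys) - 1) // 2
    med = (
        allpairs.groupby(["chrom", "start", "kind"])["dr"]
        .agg(["median", "count"])
        .unstack("kind")
    )
    counts = med["count"].fillna(0).sum(axis=1)
    med = med.loc[counts == n_pairs, "median"].reset_index()
    med.columns.name = None
    return med.rename(columns={"within": "dr_within", "between": "dr_between"})


def delta_r_outliers(medians: pd.DataFrame, z: float = 3.0) -> tuple[RegionSet, pd.DataFrame]:
    """Flag windows whose between-population Δr exceeds the within null.

    Threshold: genome-wide mean of the per-window within-population median
    Δr plus ``z`` times its SD.
    """
    w = medians["dr_within"].to_numpy()
    thr = w.mean() + z * w.std(ddof=1)
    out = medians.copy()
    out["outlier"] = out["dr_between"] > thr
    flagged = out.loc[out["outlier"], ["chrom", "start"]].copy()
    if flagged.empty:
        return RegionSet.empty(), out
    width = _window_width(medians)
    flagged["end"] = flagged["start"] + width
    return RegionSet(flagged[["chrom", "start", "end"]]), out


def _window_width(medians: pd.DataFrame) -> int:
    starts = np.sort(medians["start"].unique())
    return int(np.diff(starts).min()) if len(starts) > 1 else 100_000


# ---------------------------------------------------------------------------
# Hotspots / coldspots
# ---------------------------------------------------------------------------


def _rolling_background(logv: np.ndarray, k: int, min_bins: int):
    """Mean/SD of each bin's +/- k-bin neighbourhood, excluding the bin itself."""
    n = len(logv)
    ok = np.isfinite(logv)
    v = np.where(ok, logv, 0.0)
    v2 = np.where(ok, logv * logv, 0.0)
    c = ok.astype(float)
    cs_v = np.concatenate([[0.0], np.cumsum(v)])
    cs_v2 = np.concatenate([[0.0], np.cumsum(v2)])
    cs_c = np.concatenate([[0.0], np.cumsum(c)])
    i = np.arange(n)
    lo = np.maximum(i - k, 0)
    hi = np.minimum(i + k + 1, n)
    S = cs_v[hi] - cs_v[lo]
    Q = cs_v2[hi] - cs_v2[lo]
    C = cs_c[hi] - cs_c[lo]
    S = S - np.where(ok, logv, 0.0)
    Q = Q - np.where(ok, logv * logv, 0.0)
    C = C - ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = S / C
        var = (Q - C * mean**2) / (C - 1)
    var = np.maximum(var, 0.0)
    bad = C < min_bins
    mean[bad] = np.nan
    var[bad] = np.nan
    return mean, np.sqrt(var), C


def call_spots(track: BinnedTrack, half_window: int = 20_000, z: float = 3.0,
               merge_gap: int = 1_000, hotspot_max_len: int = 5_000,
               min_background_bins: int = 5,
               rate_floor_factor: float = 1e-3,
               population: str | None = None) -> RegionSet:
    """Call recombination hotspots and coldspots on a binned rate track.

    Each bin's log rate is compared with the mean and SD of the log rates in
    the surrounding ``+/- half_window`` bp (the bin itself excluded; at
    chromosome ends the truncated neighbourhood is used, requiring at least
    ``min_background_bins`` bins).  Bins more than ``z`` SDs above (below)
    the local mean are hotspot (coldspot) candidates; candidates of the same
    kind are merged with a ``merge_gap`` bp maximum gap, and merged hotspots
    longer than ``hotspot_max_len`` bp are removed.  Zero rates are floored
    at the smallest positive rate times ``rate_floor_factor`` before the log.

    Returns a region set with ``name`` = kind and ``score`` = peak |z|.
    """
    width = track.width
    k = half_window // width
    vals = track.df["value"].to_numpy()
    pos = vals[np.isfinite(vals) & (vals > 0)]
    floor = (pos.min() * rate_floor_factor) if len(pos) else 1.0

    rows = []
    for chrom, sub in track.df.groupby("chrom", sort=False):
        v = sub["value"].to_numpy()
        logv = np.where(np.isfinite(v), np.log(np.maximum(v, floor)), np.nan)
        mean, sd, _ = _rolling_background(logv, k, min_background_bins)
        # cumsum-based rolling stats carry float jitter; a background is
        # "flat" below this tolerance (log units)
        tol = 1e-7 * np.maximum(1.0, np.abs(mean))
        with np.errstate(invalid="ignore", divide="ignore"):
            zs = (logv - mean) / sd
        zero_sd = np.isfinite(mean) & (sd < tol)
        diff = logv - mean
        zs[zero_sd] = np.where(diff[zero_sd] > tol[zero_sd], np.inf,
                               np.where(diff[zero_sd] < -tol[zero_sd], -np.inf, 0.0))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for kind, sel in (("hotspot", zs > z), ("coldspot", zs < -z)):
            idx = np.flatnonzero(sel & np.isfinite(logv))
            for i in idx:
                rows.append((chrom, int(starts[i]), int(ends[i]), kind,
                             float(abs(zs[i]))))
    if not rows:
        out = RegionSet.empty()
        out.df["name"] = pd.Series(dtype=str)
        out.df["score"] = pd.Series(dtype=float)
        return out

    cand = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    merged_rows = []
    for kind, sub in cand.groupby("name", sort=False):
        rs = RegionSet(sub[["chrom", "start", "end"]])
        merged = merge_regions(rs, max_gap=merge_gap)
        for _, reg in merged.df.iterrows():
            if kind == "hotspot" and reg["end"] - reg["start"] > hotspot_max_len:
                continue
            peak = sub.loc[
                (sub["chrom"] == reg["chrom"])
                & (sub["start"] < reg["end"]) & (sub["end"] > reg["start"]),
                "score",
            ].max()
            merged_rows.append((reg["chrom"], reg["start"], reg["end"], kind, peak))
    if not merged_rows:
        out = RegionSet.empty()
        out.df["name"] = pd.Series(dtype=str)
        out.df["score"] = pd.Series(dtype=float)
        return out
    out = RegionSet(
        pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "name", "score"])
    )
    if population is not None:
        out.df["population"] = population
    return out


def spots_of_kind(spots: RegionSet, kind: str) -> RegionSet:
    sub = spots.df[spots.df["name"] == kind]
    if sub.empty:
        return RegionSet.empty()
    return RegionSet(sub.reset_index(drop=True))


def sharing_summary(a: RegionSet, b: RegionSet) -> dict:
    """Sharing counts and percentages between two spot sets of the same kind.

    ``shared`` counts regions of ``a`` overlapping at least one region of
    ``b`` by >= 1 bp (``shared_b`` gives the symmetric count).  Percentages
    are rounded to the nearest integer for reporting.
    """
    shared_a = int(overlap_flags(a, b).sum()) if a.n and b.n else 0
    shared_b = int(overlap_flags(b, a).sum()) if a.n and b.n else 0
    def pct(x, d):
        return round(100.0 * x / d) if d else 0
    return {
        "n_a": a.n,
        "n_b": b.n,
        "shared": shared_a,
        "shared_b": shared_b,
        "pct_of_a": pct(shared_a, a.n),
        "pct_of_b": pct(shared_a, b.n),
        "pct_of_union": pct(shared_a, a.n + b.n),
    }
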