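"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here, so the whole
pipeline is testable without any download:

* recombination landscapes for two populations as autocorrelated log-normal
  fields, with replicate-estimation noise, planted hotspots/coldspots, and
  planted between-population divergence segments;
* a pedigree-style linkage map derived from the noise-free landscape;
* two-population SNP genotypes under a Balding-Nichols allele-frequency
  model with planted high-divergence windows;
* an SV catalogue (DEL/INS/INV) with per-type length distributions and
  optional coldspot enrichment or planted frequency-divergent outliers;
* r² records around SVs following a linear LD model with per-type shifts.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .intervals import BinnedTrack, GenomeLayout, RecombinationMap, RegionSet

__all__ = [
    "LandscapeParams",
    "LandscapeSet",
    "simulate_landscapes",
    "linkage_from_landscape",
    "DivergenceParams",
    "SnpDataset",
    "simulate_genotypes",
    "SvParams",
    "SvDataset",
    "simulate_svs",
    "LdSimParams",
    "simulate_ld_records",
]

DEFAULT_LAYOUT = GenomeLayout(
    {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000, "chr4": 10_000_000}
)
"""Desk-scale stand-in genome: four 10 Mb chromosomes."""


# ---------------------------------------------------------------------------
# Recombination landscapes
# ---------------------------------------------------------------------------


@dataclass
class LandscapeParams:
    """Parameters of the two-population landscape generator.

    Log-rates follow a Gaussian field with marginal SD ``log_rate_sd`` (natural
    log units) and autocorrelation length ``autocorr_bp``, shared between the
    populations.  Hotspots/coldspots shift the local log-rate by
    ``hotspot_amp``/``-coldspot_amp`` landscape SDs and are planted in both
    populations; divergence segments shift the log-rate of population 2 only.
    Each replicate subset adds independent N(0, ``noise_sd``) estimation noise
    per bin; the default reproduces the replicate-map consistency seen in
    LD-based maps re-estimated from resampled individuals (within-population
    Spearman ~ 0.9 at 2 kb resolution).
    """

    layout: GenomeLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    bin_width: int = 2_000
    log_rate_mean: float = math.log(1e-8)
    log_rate_sd: float = 1.0
    autocorr_bp: int = 50_000
    n_replicates: int = 6
    noise_sd: float = 0.33
    n_hotspots: int = 0
    hotspot_width: int = 3_000
    hotspot_amp: float = 4.0
    n_coldspots: int = 0
    coldspot_width: int = 4_000
    coldspot_amp: float = 4.0
    divergence_segments: Sequence[tuple[str, int, int, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate subset")
        for chrom, start, end, _shift in self.divergence_segments:
            self.layout.check_interval(chrom, start, end)


@dataclass
class LandscapeSet:
    """Generated maps plus the planted truth used by recovery tests."""

    maps: dict[tuple[str, int], RecombinationMap]  # (population, replicate) -> map
    truth_fields: dict[str, BinnedTrack]  # noise-free log-rate per population
    hotspots: RegionSet
    coldspots: RegionSet
    divergence: RegionSet
    params: LandscapeParams

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(pop for pop, _ in self.maps))

    def population_maps(self, pop: str) -> list[RecombinationMap]:
        return [m for (p, _), m in self.maps.items() if p == pop]


def _plant_spots(rng, layout, width, n_spots, spot_width, bin_width) -> list[tuple[str, int, int]]:
    spots = []
    chroms = layout.chroms
    weights = np.array([layout[c] for c in chroms], float)
    weights /= weights.sum()
    for _ in range(n_spots):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        n_bins = layout[chrom] // bin_width
        # keep away from chromosome ends so the local background is complete
        lo = 15 * bin_width
        hi = n_bins * bin_width - 15 * bin_width - spot_width
        start = int(rng.integers(lo, hi))
        spots.append((chrom, start, start + spot_width))
    return spots


def simulate_landscapes(params: LandscapeParams) -> LandscapeSet:
    """Generate two populations x k replicate recombination maps plus truth.

    With ``noise_sd = 0`` and no divergence segments the two populations'
    maps are identical; the same seed always produces bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    layout, w = params.layout, params.bin_width
    sigma_bins = params.autocorr_bp / w

    hot = _plant_spots(rng, layout, w, params.n_hotspots, params.hotspot_width, w)
    cold = _plant_spots(rng, layout, w, params.n_coldspots, params.coldspot_width, w)

    base_fields: dict[str, np.ndarray] = {}
    grids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in layout.chroms:
        n_bins = math.ceil(layout[chrom] / w)
        starts = np.arange(n_bins, dtype=np.int64) * w
        ends = np.minimum(starts + w, layout[chrom])
        grids[chrom] = (starts, ends)
        white = rng.standard_normal(n_bins)
        smooth = gaussian_filter1d(white, sigma=sigma_bins, mode="reflect")
        smooth = (smooth - smooth.mean()) / smooth.std()
        f = params.log_rate_mean + params.log_rate_sd * smooth
        for (c, s, e), amp in [(s_, params.hotspot_amp) for s_ in hot] + [
            (s_, -params.coldspot_amp) for s_ in cold
        ]:
            if c == chrom:
                # per-base semantics: partially covered bins get a
                # proportionally diluted shift, as bin-averaging would give
                frac = (np.minimum(ends, e) - np.maximum(starts, s)).clip(0) / (
                    ends - starts
                )
                f += amp * params.log_rate_sd * frac
        base_fields[chrom] = f

    pop_fields: dict[str, dict[str, np.ndarray]] = {
        "pop1": {c: f.copy() for c, f in base_fields.items()},
        "pop2": {c: f.copy() for c, f in base_fields.items()},
    }
    for chrom, s, e, shift in params.divergence_segments:
        starts, ends = grids[chrom]
        sel = (starts < e) & (ends > s)
        pop_fields["pop2"][chrom][sel] += shift

    maps: dict[tuple[str, int], RecombinationMap] = {}
    for pop in ("pop1", "pop2"):
        for rep in range(params.n_replicates):
            frames = []
            for chrom in layout.chroms:
                starts, ends = grids[chrom]
                f = pop_fields[pop][chrom]
                noise = (
                    rng.normal(0.0, params.noise_sd, size=f.shape)
                    if params.noise_sd > 0
                    else 0.0
                )
                frames.append(
                    pd.DataFrame(
                        {"chrom": chrom, "start": starts, "end": ends,
                         "rate": np.exp(f + noise)}
                    )
                )
            maps[(pop, rep)] = RecombinationMap(
                pd.concat(frames, ignore_index=True), population=pop, subset=rep
            )

    truth_fields = {
        pop: BinnedTrack(
            pd.concat(
                [
                    pd.DataFrame({"chrom": c, "start": grids[c][0],
                                  "end": grids[c][1], "value": fields[c]})
                    for c in layout.chroms
                ],
                ignore_index=True,
            ),
            w,
        )
        for pop, fields in pop_fields.items()
    }

    def _regions(spots, names=None):
        if not spots:
            return RegionSet.empty()
        return RegionSet(pd.DataFrame(spots, columns=["chrom", "start", "end"]))

    div = RegionSet.empty()
    if params.divergence_segments:
        div = RegionSet(
            pd.DataFrame(
                [(c, s, e) for c, s, e, _ in params.divergence_segments],
                columns=["chrom", "start", "end"],
            )
        )
    return LandscapeSet(maps, truth_fields, _regions(hot), _regions(cold), div, params)


def linkage_from_landscape(landscapes: LandscapeSet, window: int = 100_000,
                           noise_sd: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Derive a pedigree-style linkage map (cM/Mb) from the true landscape.

    The population-averaged noise-free rate is averaged into ``window`` bp
    windows and converted to cM/Mb (1e-8 per bp per generation = 1 cM/Mb),
    with independent log-normal measurement noise.  This emulates an
    independent meiotic map that tracks the LD-based landscape imperfectly.
    """
    rng = np.random.default_rng(seed)
    pops = list(landscapes.truth_fields)
    frames = []
    for chrom in landscapes.params.layout.chroms:
        tracks = [landscapes.truth_fields[p] for p in pops]
        mean_rate = np.mean(
            [np.exp(t.values_for(chrom)) for t in tracks], axis=0
        )
        sub = tracks[0].df[tracks[0].df["chrom"] == chrom]
        frames.append(pd.DataFrame({"chrom": chrom, "start": sub["start"].to_numpy(),
                                    "end": sub["end"].to_numpy(), "rate": mean_rate}))
    fine = RecombinationMap(pd.concat(frames, ignore_index=True))
    from .intervals import bin_average

    track = bin_average(fine, window, landscapes.params.layout)
    cmmb = track.df["value"].to_numpy() * 1e8
    cmmb = cmmb * np.exp(rng.normal(0.0, noise_sd, size=cmmb.shape))
    out = track.df.rename(columns={"value": "cmmb"}).copy()
    out["cmmb"] = cmmb
    return out


# ---------------------------------------------------------------------------
# Two-population SNP genotypes (Balding-Nichols)
# ---------------------------------------------------------------------------


@dataclass
class DivergenceParams:
    """Parameters of the two-population genotype generator.

    Per SNP an ancestral frequency ``p`` is drawn uniformly, then each
    population's frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``f_base`` outside and ``f_high`` inside the planted windows
    (Balding-Nichols F-model).  Diploid genotypes are binomial given the
    population frequency.  SNPs with a pooled minor allele frequency below
    ``maf_min`` in the realized sample are dropped, mirroring the usual
    population-genomic MAF filter.
    """

    layout: GenomeLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    n_snps: int = 20_000
    f_base: float = 0.02
    f_high: float = 0.4
    n_planted: int = 10
    planted_window: int = 100_000
    planted_windows: Sequence[tuple[str, int, int]] | None = None
    n1: int = 40
    n2: int = 40
    missing_rate: float = 0.0
    maf_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_base < 1 and 0 < self.f_high < 1):
            raise ValueError("F parameters must lie in (0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least two diploids per population")


@dataclass
class SnpDataset:
    """Simulated SNPs with per-population genotype summaries.

    ``df`` has one row per SNP: chrom, pos, per-population called-diploid
    counts (n1/n2), alt-allele counts (ac1/ac2), heterozygote counts
    (het1/het2), and the planted-window truth flag.  ``G1``/``G2`` are the
    underlying dosage matrices (sites x diploids, -1 = missing).
    """

    df: pd.DataFrame
    G1: np.ndarray
    G2: np.ndarray
    planted: RegionSet
    layout: GenomeLayout
    params: DivergenceParams


def _count_pop(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    called = G >= 0
    n = called.sum(axis=1)
    ac = np.where(called, G, 0).sum(axis=1)
    het = (G == 1).sum(axis=1)
    return n, ac, het


def simulate_genotypes(params: DivergenceParams) -> SnpDataset:
    """Generate the SNP dataset; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    layout = params.layout

    if params.planted_windows is not None:
        planted = list(params.planted_windows)
    else:
        planted = []
        chroms = layout.chroms
        weights = np.array([layout[c] for c in chroms], float)
        weights /= weights.sum()
        taken: set[tuple[str, int]] = set()
        while len(planted) < params.n_planted:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            n_win = layout[chrom] // params.planted_window
            i = int(rng.integers(0, n_win))
            if (chrom, i) in taken:
                continue
            taken.add((chrom, i))
            planted.append((chrom, i * params.planted_window,
                            (i + 1) * params.planted_window))
    planted_rs = (
        RegionSet(pd.DataFrame(planted, columns=["chrom", "start", "end"]))
        if planted
        else RegionSet.empty()
    )

    chroms = layout.chroms
    weights = np.array([layout[c] for c in chroms], float)
    weights /= weights.sum()
    counts = rng.multinomial(params.n_snps, weights)
    frames = []
    for chrom, k in zip(chroms, counts):
        pos = np.sort(rng.choice(layout[chrom], size=k, replace=False))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    df = pd.concat(frames, ignore_index=True)

    in_planted = np.zeros(len(df), dtype=bool)
    for chrom, s, e in planted:
        sel = (df["chrom"] == chrom) & (df["pos"] >= s) & (df["pos"] < e)
        in_planted |= sel.to_numpy()

    p_anc = rng.uniform(0.05, 0.95, size=len(df))
    F = np.where(in_planted, params.f_high, params.f_base)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)

    G1 = rng.binomial(2, p1[:, None], size=(len(df), params.n1)).astype(np.int8)
    G2 = rng.binomial(2, p2[:, None], size=(len(df), params.n2)).astype(np.int8)
    if params.missing_rate > 0:
        G1[rng.random(G1.shape) < params.missing_rate] = -1
        G2[rng.random(G2.shape) < params.missing_rate] = -1

    n1, ac1, het1 = _count_pop(G1)
    n2, ac2, het2 = _count_pop(G2)
    tot_n = 2 * (n1 + n2)
    with np.errstate(invalid="ignore"):
        pooled = np.where(tot_n > 0, (ac1 + ac2) / np.maximum(tot_n, 1), 0.0)
    maf = np.minimum(pooled, 1 - pooled)
    keep = (maf >= params.maf_min) & (n1 >= 2) & (n2 >= 2)

    out = df.loc[keep].reset_index(drop=True)
    out["n1"], out["ac1"], out["het1"] = n1[keep], ac1[keep], het1[keep]
    out["n2"], out["ac2"], out["het2"] = n2[keep], ac2[keep], het2[keep]
    out["in_planted"] = in_planted[keep]
    return SnpDataset(out, G1[keep], G2[keep], planted_rs, layout, params)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------


@dataclass
class SvParams:
    """Parameters of the SV catalogue generator.

    Per-type counts follow the observed catalogue composition at reduced
    scale (deletions ~ insertions >> inversions); lengths are log-normal per
    type with medians around 0.2 kb (DEL), 0.25 kb (INS) and 2.5 kb (INV).
    Population frequencies follow the same Balding-Nichols model as SNPs;
    ``n_outliers`` SVs get a planted frequency gap ``outlier_gap`` between
    populations.  ``frac_in_coldspots`` of SVs are placed uniformly inside a
    supplied coldspot set instead of uniformly along the genome.
    """

    layout: GenomeLayout = field(default_factory=lambda: DEFAULT_LAYOUT)
    n_del: int = 200
    n_ins: int = 180
    n_inv: int = 5
    len_median: Mapping[str, float] = field(
        default_factory=lambda: {"DEL": 200.0, "INS": 250.0, "INV": 2500.0}
    )
    len_log_sd: Mapping[str, float] = field(
        default_factory=lambda: {"DEL": 0.6, "INS": 0.6, "INV": 1.0}
    )
    len_min: int = 50
    f_base: float = 0.02
    n_outliers: int = 0
    outlier_gap: float = 0.8
    frac_in_coldspots: float = 0.0
    n1: int = 40
    n2: int = 40
    maf_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_del, self.n_ins, self.n_inv) < 0:
            raise ValueError("SV counts must be >= 0")
        if not 0 <= self.frac_in_coldspots <= 1:
            raise ValueError("frac_in_coldspots must lie in [0, 1]")


@dataclass
class SvDataset:
    """Simulated SV catalogue with genotype summaries and planted truth."""

    df: pd.DataFrame
    G1: np.ndarray
    G2: np.ndarray
    layout: GenomeLayout
    params: SvParams


def _place_uniform(rng, layout, n):
    chroms = layout.chroms
    weights = np.array([layout[c] for c in chroms], float)
    weights /= weights.sum()
    idx = rng.choice(len(chroms), size=n, p=weights)
    pos = np.array([rng.integers(0, layout[chroms[i]]) for i in idx], dtype=np.int64)
    return np.array(chroms, dtype=object)[idx], pos


def _place_in_regions(rng, regions: RegionSet, n):
    lens = (regions.df["end"] - regions.df["start"]).to_numpy(np.int64)
    p = lens / lens.sum()
    idx = rng.choice(len(lens), size=n, p=p)
    offs = np.array([rng.integers(0, lens[i]) for i in idx], dtype=np.int64)
    chrom = regions.df["chrom"].to_numpy(object)[idx]
    pos = regions.df["start"].to_numpy(np.int64)[idx] + offs
    return chrom, pos


def simulate_svs(params: SvParams, coldspots: RegionSet | None = None) -> SvDataset:
    """Generate the SV catalogue; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    layout = params.layout
    types = (["DEL"] * params.n_del + ["INS"] * params.n_ins + ["INV"] * params.n_inv)
    n = len(types)
    if params.frac_in_coldspots > 0 and (coldspots is None or coldspots.n == 0):
        raise ValueError("frac_in_coldspots > 0 requires a non-empty coldspot set")

    in_cold = rng.random(n) < params.frac_in_coldspots
    chrom = np.empty(n, dtype=object)
    pos = np.zeros(n, dtype=np.int64)
    if in_cold.any():
        c, p = _place_in_regions(rng, coldspots, int(in_cold.sum()))
        chrom[in_cold], pos[in_cold] = c, p
    if (~in_cold).any():
        c, p = _place_uniform(rng, layout, int((~in_cold).sum()))
        chrom[~in_cold], pos[~in_cold] = c, p

    length = np.array(
        [
            max(params.len_min,
                int(rng.lognormal(math.log(params.len_median[t]),
                                  params.len_log_sd[t])))
            for t in types
        ],
        dtype=np.int64,
    )
    # keep reference spans inside the chromosome
    for i, t in enumerate(types):
        limit = layout[chrom[i]]
        if t in ("DEL", "INV") and pos[i] + length[i] > limit:
            pos[i] = max(0, limit - length[i])
        pos[i] = min(pos[i], limit - 2)

    p_anc = rng.uniform(0.05, 0.95, size=n)
    F = params.f_base
    p1 = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
    p2 = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
    planted = np.zeros(n, dtype=bool)
    if params.n_outliers > 0:
        # plant divergent frequencies on deletions/insertions only, like the
        # outliers observed among short SV classes
        cand = np.flatnonzero(np.array(types) != "INV")
        pick = rng.choice(cand, size=min(params.n_outliers, len(cand)), replace=False)
        planted[pick] = True
        lo = (1 - params.outlier_gap) / 2
        p1[pick] = 1 - lo
        p2[pick] = lo

    G1 = rng.binomial(2, p1[:, None], size=(n, params.n1)).astype(np.int8)
    G2 = rng.binomial(2, p2[:, None], size=(n, params.n2)).astype(np.int8)
    n1, ac1, het1 = _count_pop(G1)
    n2, ac2, het2 = _count_pop(G2)

    df = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "svtype": types, "length": length,
         "p1": p1, "p2": p2, "n1": n1, "ac1": ac1, "het1": het1,
         "n2": n2, "ac2": ac2, "het2": het2, "planted_outlier": planted}
    )
    if params.maf_min > 0:
        pooled = (df["ac1"] + df["ac2"]) / (2 * (df["n1"] + df["n2"]))
        maf = np.minimum(pooled, 1 - pooled)
        keep = (maf >= params.maf_min).to_numpy()
        df = df.loc[keep].reset_index(drop=True)
        G1, G2 = G1[keep], G2[keep]
    order = df.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    df = df.loc[order].reset_index(drop=True)
    return SvDataset(df, G1[order], G2[order], layout, params)


# ---------------------------------------------------------------------------
# LD around SVs
# ---------------------------------------------------------------------------


@dataclass
class LdSimParams:
    """Linear model generating r² for SNP pairs flanking SVs.

    r² = intercept + b_prop * proportion_covered + type_shift[type]
       + chromosome intercept ~ N(0, chrom_sd) + N(0, noise_sd), clipped to
    [0, 1].  ``type_shift`` plants per-type LD elevation (e.g. inversions).
    """

    intercept: float = 0.05
    b_prop: float = 0.10
    type_shift: Mapping[str, float] = field(
        default_factory=lambda: {"DEL": 0.0, "INS": 0.0, "INV": 0.0}
    )
    chrom_sd: float = 0.02
    noise_sd: float = 0.08
    flank: int = 5_000
    seed: int = 0


def simulate_ld_records(sv_df: pd.DataFrame, snp_pos: pd.DataFrame,
                        params: LdSimParams) -> pd.DataFrame:
    """r² records (chrom, posA, posB, r2) for the SNP pairs flanking each SV.

    ``snp_pos`` needs chrom and pos columns.  Pairs are the nearest SNP on
    each side of the SV's reference span within ``params.flank`` bp; SVs
    without both flanks yield no record.
    """
    from .svs import flanking_pairs

    rng = np.random.default_rng(params.seed)
    pairs = flanking_pairs(sv_df, snp_pos, flank=params.flank)
    if pairs.empty:
        return pd.DataFrame(columns=["chrom", "posA", "posB", "r2"])
    u = {c: rng.normal(0.0, params.chrom_sd) for c in dict.fromkeys(pairs["chrom"])}
    prop = pairs["length"].to_numpy(float) / (
        pairs["posB"].to_numpy(float) - pairs["posA"].to_numpy(float)
    )
    shift = pairs["svtype"].map(params.type_shift).to_numpy(float)
    r2 = (
        params.intercept
        + params.b_prop * prop
        + shift
        + pairs["chrom"].map(u).to_numpy(float)
        + rng.normal(0.0, params.noise_sd, size=len(pairs))
    )
    out = pairs[["chrom", "posA", "posB"]].copy()
    out["r2"] = np.clip(r2, 0.0, 1.0)
    return out.drop_duplicates(subset=["chrom", "posA", "posB"]).reset_index(drop=True)
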