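"""End-to-end orchestration: config, staging, and the JSON report.

``run_all`` executes the full analysis on synthetic inputs (or user files
for the map/VCF/BED inputs): landscape divergence (PRDI, Δr, spots), the
recombination-stratified F_ST window scan with candidate-region overlap
testing, the diversity and LD-map residual models, and the SV analyses.
Every analysis tunable defaults to the study values (2 kb bins, 5 Mb
correlation windows, 100 kb scan windows, >= 10 SNPs per window, 99th
percentile outliers, 0.05 binomial cut, +/- 20 kb spot background with
z = 3, 1 kb merge gap, 5 kb hotspot cap, 500 window permutations, 10,000
spot shuffles, 5 kb SV flanks).  The run writes a machine-readable JSON
report with the config echoed for provenance, plus BED/TSV tracks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffscan, diversity, landscape, simulate, svs
from .intervals import (
    BinnedTrack,
    GenomeLayout,
    RegionSet,
    bin_average,
    linkage_to_track,
    merge_regions,
    overlap_flags as _ovf,
    write_bed,
)

log = logging.getLogger("recdiff")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All pipeline tunables with study defaults, plus generator sizes."""

    seed: int = 1
    outdir: str = "recdiff_out"

    # analysis tunables (study defaults)
    bin_width: int = 2_000
    corr_window: int = 5_000_000
    scan_window: int = 100_000
    min_snps_per_window: int = 10
    outlier_quantile: float = 0.99
    binom_alpha: float = 0.05
    spot_half_window: int = 20_000
    spot_z: float = 3.0
    spot_merge_gap: int = 1_000
    hotspot_max_len: int = 5_000
    n_perm_overlap: int = 500
    n_shuffles_spots: int = 10_000
    sv_flank: int = 5_000
    delta_r_eps: float = 1e-12

    # synthetic genome and generator sizes (desk scale)
    chrom_length: int = 10_000_000
    n_chroms: int = 4
    n_replicates: int = 6
    noise_sd: float = 0.33
    n_hotspots: int = 20
    n_coldspots: int = 20
    n_divergence_segments: int = 4
    divergence_shift: float = 1.5
    n_snps: int = 20_000
    f_base: float = 0.02
    f_high: float = 0.4
    n_planted_windows: int = 10
    n_diploids: int = 40
    missing_rate: float = 0.02
    n_del: int = 200
    n_ins: int = 180
    n_inv: int = 20
    n_sv_outliers: int = 8
    frac_sv_in_coldspots: float = 0.2
    n_candidate_regions: int = 25

    # optional external inputs; when None the corresponding stage simulates
    snp_vcf: str | None = None
    sv_vcf: str | None = None
    linkage_tsv: str | None = None
    candidates_bed: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        )


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def _divergence_segments(cfg: RunConfig, rng: np.random.Generator):
    """Plant one ~2 Mb shifted segment inside each of several 5 Mb windows."""
    layout = cfg.layout()
    segs = []
    windows = [
        (c, ws)
        for c in layout.chroms
        for ws in range(0, layout[c] - cfg.corr_window + 1, cfg.corr_window)
    ]
    pick = rng.choice(len(windows), size=min(cfg.n_divergence_segments, len(windows)),
                      replace=False)
    for i in pick:
        chrom, ws = windows[i]
        start = ws + int(rng.integers(500_000, cfg.corr_window - 2_500_000))
        segs.append((chrom, start, start + 2_000_000, cfg.divergence_shift))
    return segs


def _mean_log_track(maps, bin_width, layout) -> BinnedTrack:
    """Replicate-averaged rate track (geometric mean across replicates)."""
    tracks = [bin_average(m, bin_width, layout) for m in maps]
    with np.errstate(divide="ignore"):
        logs = np.array([np.log(t.df["value"].to_numpy()) for t in tracks])
    mean_rate = np.exp(np.nanmean(logs, axis=0))
    df = tracks[0].df.copy()
    df["value"] = mean_rate
    return BinnedTrack(df, bin_width)


def _candidates(cfg: RunConfig, planted: RegionSet, rng) -> RegionSet:
    """Synthetic candidate ("repeated") regions: planted windows plus noise.

    Candidate regions of 100-300 kb are placed at random; a copy of each
    planted window is included so the overlap test has signal to find.
    """
    layout = cfg.layout()
    rows = [tuple(r) for r in planted.df[["chrom", "start", "end"]].itertuples(index=False)]
    chroms = layout.chroms
    for _ in range(cfg.n_candidate_regions):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = int(rng.integers(100_000, 300_000))
        start = int(rng.integers(0, layout[chrom] - size))
        rows.append((chrom, start, start + size))
    return merge_regions(RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])),
                         max_gap=0)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and return (and write) the report dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()
    from . import __version__

    report: dict = {"version": __version__, "config": cfg.to_dict(),
                    "stages": {}}

    # -- stage 1: landscapes ------------------------------------------------
    log.info("stage landscapes: simulating %d replicate maps per population",
             cfg.n_replicates)
    seg = _divergence_segments(cfg, rng)
    lp = simulate.LandscapeParams(
        layout=layout, bin_width=cfg.bin_width, n_replicates=cfg.n_replicates,
        noise_sd=cfg.noise_sd, n_hotspots=cfg.n_hotspots,
        n_coldspots=cfg.n_coldspots, divergence_segments=seg,
        seed=_child_seed(rng),
    )
    emp = simulate.simulate_landscapes(lp)
    neutral_params = dataclasses.replace(lp, divergence_segments=(),
                                         seed=_child_seed(rng))
    neu = simulate.simulate_landscapes(neutral_params)

    tracks_emp = {k: bin_average(m, cfg.bin_width, layout) for k, m in emp.maps.items()}
    tracks_neu = {k: bin_average(m, cfg.bin_width, layout) for k, m in neu.maps.items()}

    panel_emp = landscape.window_spearman(tracks_emp, cfg.corr_window)
    panel_neu = landscape.window_spearman(tracks_neu, cfg.corr_window)
    me = landscape.compute_me(panel_emp)
    ms = landscape.compute_me(panel_neu)
    prdi = landscape.compute_prdi(me, ms)
    profile = landscape.prdi_profile(panel_emp, panel_neu)
    profile.to_csv(outdir / "prdi_profile.tsv", sep="\t", index=False)

    meds = landscape.delta_r_medians(tracks_emp, cfg.scan_window, cfg.delta_r_eps)
    dr_outliers, dr_table = landscape.delta_r_outliers(meds)
    write_bed(dr_outliers, outdir / "delta_r_outliers.bed")

    report["stages"]["landscape"] = {
        "me": me, "ms": ms, "prdi": prdi.prdi,
        "prdi_profile_max": (float(profile["prdi"].max()) if len(profile) else None),
        "n_delta_r_windows": int(len(dr_table)),
        "n_delta_r_outliers": int(dr_table["outlier"].sum()),
        "median_rho": {
            kind: float(panel_emp.loc[panel_emp["kind"] == kind, "rho"].median())
            for kind in ("within_pop1", "within_pop2", "between")
        },
    }

    # -- stage 2: hotspots / coldspots --------------------------------------
    log.info("stage spots: calling hotspots and coldspots per population")
    spot_sets = {}
    for pop in emp.populations:
        track = _mean_log_track(emp.population_maps(pop), cfg.bin_width, layout)
        spot_sets[pop] = landscape.call_spots(
            track, cfg.spot_half_window, cfg.spot_z, cfg.spot_merge_gap,
            cfg.hotspot_max_len, population=pop,
        )
        write_bed(spot_sets[pop], outdir / f"spots_{pop}.bed")
    sharing = {}
    for kind in ("hotspot", "coldspot"):
        a = landscape.spots_of_kind(spot_sets["pop1"], kind)
        b = landscape.spots_of_kind(spot_sets["pop2"], kind)
        sharing[kind] = landscape.sharing_summary(a, b)
    report["stages"]["spots"] = sharing

    # -- stage 3: F_ST scan -------------------------------------------------
    log.info("stage scan: SNP F_ST windows with recombination bins")
    if cfg.linkage_tsv is not None:
        from .intervals import read_linkage_map

        linkage = read_linkage_map(cfg.linkage_tsv)
        linkage_track = linkage_to_track(linkage, cfg.scan_window, layout)
    else:
        linkage = simulate.linkage_from_landscape(emp, cfg.scan_window,
                                                  seed=_child_seed(rng))
        # generated linkage windows already live on the scan grid
        linkage_track = BinnedTrack(
            linkage.rename(columns={"cmmb": "value"}), cfg.scan_window
        )

    dp = simulate.DivergenceParams(
        layout=layout, n_snps=cfg.n_snps, f_base=cfg.f_base, f_high=cfg.f_high,
        n_planted=cfg.n_planted_windows, n1=cfg.n_diploids, n2=cfg.n_diploids,
        missing_rate=cfg.missing_rate, seed=_child_seed(rng),
    )
    snps = simulate.simulate_genotypes(dp)
    log.info("scan: %d SNPs retained after the MAF filter", len(snps.df))
    snp_df = diffscan.add_fst(snps.df)
    snp_df = diffscan.attach_windows_and_bins(snp_df, linkage_track, cfg.scan_window)
    snp_df = diffscan.binwise_outliers(snp_df, cfg.outlier_quantile)
    snp_df[["chrom", "pos", "fst", "bin", "outlier"]].to_csv(
        outdir / "snp_fst.tsv", sep="\t", index=False
    )
    scan = diffscan.window_enrichment(snp_df, cfg.scan_window,
                                      cfg.min_snps_per_window, cfg.binom_alpha)
    scan.windows.to_csv(outdir / "window_scan.tsv", sep="\t", index=False)
    write_bed(scan.merged, outdir / "enriched_regions.bed")

    candidates = _candidates(cfg, snps.planted, rng)
    write_bed(candidates, outdir / "candidate_regions.bed")
    ov_test = diffscan.repeated_overlap_test(
        scan.enriched_regions, scan.background_regions, candidates, layout,
        cfg.n_perm_overlap, rng,
    ) if cfg.n_perm_overlap > 0 else None
    ov_pct = diffscan.overlap_percentages(scan.enriched_regions, candidates)

    planted_hit = (
        _ovf(snps.planted, scan.enriched_regions) if snps.planted.n else np.zeros(0, bool)
    )
    report["stages"]["scan"] = {
        "n_snps": int(len(snp_df)),
        "p0": scan.p0,
        "n_windows": int(len(scan.windows)),
        "n_enriched": scan.n_enriched,
        "n_enriched_merged": scan.n_enriched_merged,
        "chi2_bins": {"statistic": scan.chi2_bins[0], "p": scan.chi2_bins[1]},
        "snp_count_corr": {"r": scan.snp_count_corr[0], "p": scan.snp_count_corr[1]},
        "planted_window_recovery": (
            float(planted_hit.mean()) if len(planted_hit) else None
        ),
        "overlap_percentages": ov_pct,
        "overlap_test": (
            {
                "chi2": ov_test.chi2,
                "perm_mean": float(ov_test.null.mean()),
                "perm_sd": float(ov_test.null.std(ddof=1)),
                "empirical_p": ov_test.p_value,
                "p_label": ov_test.p_label,
            }
            if ov_test is not None
            else {"skipped": True}
        ),
    }

    # -- stage 4: diversity and residuals -----------------------------------
    log.info("stage diversity: windowed pi, F_ST models, map residuals")
    pi1 = diversity.windowed_pi(snp_df, 1, cfg.scan_window, layout)
    pi2 = diversity.windowed_pi(snp_df, 2, cfg.scan_window, layout)
    t_pi, p_pi = diversity.pi_population_test(pi1, pi2)
    fst_track = diversity.windowed_fst(snp_df, cfg.scan_window, layout)

    models = {}
    for pop, pi_track in (("pop1", pi1), ("pop2", pi2)):
        frame = pd.DataFrame(
            {
                "fst": fst_track.df["value"],
                "rec": linkage_track.df["value"],
                "pi": pi_track.df["value"],
            }
        )
        models[pop] = diversity.fst_pi_recomb_model(frame).to_dict()

    rho_track = _mean_log_track(
        emp.population_maps("pop1") + emp.population_maps("pop2"),
        cfg.scan_window, layout,
    )
    resid = diversity.ld_map_residuals(rho_track, linkage_track)
    windows_rs = RegionSet(resid[["chrom", "start", "end"]].copy())
    enr_flag = _ovf(windows_rs, scan.enriched_regions) if scan.enriched_regions.n else np.zeros(windows_rs.n, bool)
    cand_flag = _ovf(windows_rs, candidates) if candidates.n else np.zeros(windows_rs.n, bool)
    cats = pd.Series(
        np.where(enr_flag & cand_flag, "outlier_repeated",
                 np.where(enr_flag, "outlier", "background"))
    )
    resid_out = resid.copy()
    resid_out["category"] = cats.to_numpy()
    resid_out.to_csv(outdir / "map_residuals.tsv", sep="\t", index=False)
    rtests = diversity.residual_tests(resid, pi1, pi2, fst_track, cats)

    report["stages"]["diversity"] = {
        "mean_pi": {"pop1": float(np.nanmean(pi1.df["value"])),
                    "pop2": float(np.nanmean(pi2.df["value"]))},
        "pi_t_test": {"t": t_pi, "p": p_pi},
        "fst_models": models,
        "residual_tests": {
            k: v for k, v in rtests.items() if k != "degenerate"
        },
    }

    # -- stage 5: structural variants ---------------------------------------
    log.info("stage svs: catalogue, outliers, LD model, spot enrichment")
    svp = simulate.SvParams(
        layout=layout, n_del=cfg.n_del, n_ins=cfg.n_ins, n_inv=cfg.n_inv,
        n_outliers=cfg.n_sv_outliers,
        frac_in_coldspots=(cfg.frac_sv_in_coldspots if emp.coldspots.n else 0.0),
        n1=cfg.n_diploids, n2=cfg.n_diploids, seed=_child_seed(rng),
    )
    sv_data = simulate.simulate_svs(svp, emp.coldspots)
    sv_df = svs.add_sv_fst(sv_data.df)
    sv_df = svs.sv_fst_outliers(sv_df, cfg.outlier_quantile)

    fisher = {
        "all": svs.sv_overlap_fisher(sv_df, scan.enriched_regions),
        "large": svs.sv_overlap_fisher(sv_df, scan.enriched_regions,
                                       size_class="large"),
        "small": svs.sv_overlap_fisher(sv_df, scan.enriched_regions,
                                       size_class="small"),
    }
    density = svs.sv_density_control(sv_df, scan.windows, cfg.scan_window)

    ld_models = {}
    for pop, shift in (("pop1", 0.05), ("pop2", 0.05)):
        ld_params = simulate.LdSimParams(
            type_shift={"DEL": 0.0, "INS": 0.0, "INV": shift},
            flank=cfg.sv_flank, seed=_child_seed(rng),
        )
        ld_records = simulate.simulate_ld_records(sv_df, snp_df[["chrom", "pos"]],
                                                  ld_params)
        feats = svs.build_ld_features(sv_df, snp_df[["chrom", "pos"]], ld_records,
                                      cfg.sv_flank)
        ld_models[pop] = (
            svs.fit_ld_model(feats).to_dict()
            if len(feats) >= 10
            else {"skipped": "too few features"}
        )

    spot_cats = {}
    for kind in ("hotspot", "coldspot"):
        a = landscape.spots_of_kind(spot_sets["pop1"], kind)
        b = landscape.spots_of_kind(spot_sets["pop2"], kind)
        if a.n and b.n:
            shared_flags = _ovf(a, b)
            shared = RegionSet(a.df.loc[shared_flags, ["chrom", "start", "end"]]
                               .reset_index(drop=True)) if shared_flags.any() else RegionSet.empty()
            spec_rows = pd.concat(
                [a.df.loc[~shared_flags, ["chrom", "start", "end"]],
                 b.df.loc[~_ovf(b, a), ["chrom", "start", "end"]]]
            ).reset_index(drop=True)
            specific = RegionSet(spec_rows) if len(spec_rows) else RegionSet.empty()
        else:
            shared = RegionSet.empty()
            both = pd.concat([a.df, b.df]).reset_index(drop=True)
            specific = RegionSet(both[["chrom", "start", "end"]]) if len(both) else RegionSet.empty()
        for label, rs in ((f"shared_{kind}", shared), (f"specific_{kind}", specific)):
            if rs.n and cfg.n_shuffles_spots > 0:
                spot_cats[label] = svs.spot_enrichment(
                    sv_df, rs, layout, cfg.n_shuffles_spots, rng
                ).to_dict()
            else:
                spot_cats[label] = {"skipped": "no regions" if not rs.n else "no shuffles"}

    report["stages"]["svs"] = {
        "catalogue": svs.catalogue_summary(sv_df),
        "n_outliers": int(sv_df["outlier"].sum()),
        "planted_outliers_recovered": int(
            (sv_df["outlier"] & sv_df["planted_outlier"]).sum()
        ),
        "fisher": fisher,
        "density_control": {"rho": density["rho"], "p": density["p"]},
        "ld_models": ld_models,
        "spot_enrichment": spot_cats,
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    log.info("report written to %s", outdir / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
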