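"""SV catalogue, outliers, Fisher overlap, LD features and spot enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recdiff import simulate, svs
from recdiff.intervals import GenomeLayout, RegionSet
from conftest import regions
import _oracles


def _sv_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "svtype", "length"])


class TestCatalogueSummary:
    def test_counts_sum_to_total(self):
        df = _sv_df([("chr1", 100, "DEL", 200), ("chr1", 500, "INS", 80),
                     ("chr2", 100, "INV", 5000), ("chr2", 900, "DEL", 150)])
        out = svs.catalogue_summary(df)
        assert out["total"] == 4
        assert out["by_type"]["DEL"]["count"] == 2
        assert out["by_type"]["DEL"]["mean_length"] == pytest.approx(175.0)

    def test_empty_catalogue_all_zero(self):
        out = svs.catalogue_summary(_sv_df([]))
        assert out["total"] == 0
        assert all(v["count"] == 0 for v in out["by_type"].values())

    def test_unknown_type_rejected_with_warning(self):
        df = _sv_df([("chr1", 100, "DEL", 200), ("chr1", 500, "DUP", 80)])
        with pytest.warns(UserWarning, match="unknown SVTYPE"):
            out = svs.catalogue_summary(df)
        assert out["total"] == 1


class TestSvOutliers:
    def test_about_one_percent_flagged(self, rng):
        df = pd.DataFrame({"fst": rng.beta(0.5, 10, size=2000)})
        out = svs.sv_fst_outliers(df)
        assert abs(out["outlier"].mean() - 0.01) < 0.005

    def test_all_equal_none_flagged(self):
        df = pd.DataFrame({"fst": np.full(100, 0.2)})
        assert not svs.sv_fst_outliers(df)["outlier"].any()


class TestFisherOverlap:
    @staticmethod
    def _catalogue(n_out_in, n_out_tot, n_bg_in, n_bg_tot):
        rows = []
        # enriched region on chr1 [0, 1e6); "inside" SVs placed there
        for i in range(n_out_tot):
            inside = i < n_out_in
            rows.append(("chr1", 1000 + i * 40 if inside else 2_000_000 + i * 40,
                         "DEL", 30, True))
        for i in range(n_bg_tot):
            inside = i < n_bg_in
            rows.append(("chr1", 500_000 + i * 4 if inside else 5_000_000 + i * 40,
                         "INS", 30, False))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "svtype", "length",
                                         "outlier"])
        return df, regions(("chr1", 0, 1_000_000))

    def test_equal_proportions_or_one(self):
        df, enriched = self._catalogue(10, 20, 50, 100)
        out = svs.sv_overlap_fisher(df, enriched)
        assert out["odds_ratio"] == pytest.approx(1.0)

    def test_toy_table_matches_hypergeometric_enumeration(self):
        df, enriched = self._catalogue(3, 4, 2, 6)
        out = svs.sv_overlap_fisher(df, enriched)
        assert out["table"] == [[3, 1], [2, 4]]
        assert out["p"] == pytest.approx(
            _oracles.fisher_two_sided([[3, 1], [2, 4]]), rel=1e-9
        )

    def test_size_stratification(self):
        df, enriched = self._catalogue(5, 10, 10, 50)
        df.loc[::2, "length"] = 2_000
        small = svs.sv_overlap_fisher(df, enriched, size_class="small")
        large = svs.sv_overlap_fisher(df, enriched, size_class="large")
        assert small["n"] + large["n"] == len(df)

    def test_zero_margin_noted(self):
        df, enriched = self._catalogue(0, 5, 0, 10)
        out = svs.sv_overlap_fisher(df, enriched)
        assert "note" in out


class TestDensityControl:
    WINDOWS = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 100_000],
         "end": [100_000, 200_000], "p": [0.01, 0.5]}
    )

    def test_no_svs_flagged_degenerate(self):
        out = svs.sv_density_control(_sv_df([]), self.WINDOWS)
        assert out["rho"] is None

    def test_occupancy_rule(self):
        df = _sv_df([("chr1", 10_000, "INS", 50_000),  # counts 1 bp
                     ("chr1", 120_000, "DEL", 5_000),  # counts 1 bp
                     ("chr1", 130_000, "INV", 20_000)])  # counts its length
        out = svs.sv_density_control(df, self.WINDOWS)
        assert out["density"][0] == pytest.approx(1 / 100_000)
        assert out["density"][1] == pytest.approx((1 + 20_000) / 100_000)

    def test_null_association_weak(self, rng):
        rows = [("chr1", int(p), "DEL", 100)
                for p in rng.choice(10_000_000, 400, replace=False)]
        win = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(100) * 100_000,
             "end": (np.arange(100) + 1) * 100_000,
             "p": rng.uniform(size=100)}
        )
        out = svs.sv_density_control(_sv_df(rows), win)
        assert abs(out["rho"]) < 0.3


class TestLdFeatures:
    def test_proportion_covered_formula(self):
        sv = _sv_df([("chr1", 1_200, "DEL", 400)])
        snps = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1_000, 2_000]})
        ld = pd.DataFrame({"chrom": ["chr1"], "posA": [1_000], "posB": [2_000],
                           "r2": [0.4]})
        feats = svs.build_ld_features(sv, snps, ld)
        assert feats["prop_covered"].iloc[0] == pytest.approx(400 / 1000)

    def test_insertion_proportion_may_exceed_one(self):
        sv = _sv_df([("chr1", 1_500, "INS", 5_000)])
        snps = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1_000, 2_000]})
        ld = pd.DataFrame({"chrom": ["chr1"], "posA": [1_000], "posB": [2_000],
                           "r2": [0.4]})
        feats = svs.build_ld_features(sv, snps, ld)
        assert feats["prop_covered"].iloc[0] == pytest.approx(5.0)

    def test_missing_flank_drops_sv(self):
        sv = _sv_df([("chr1", 50_000, "DEL", 400)])
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [51_000]})  # right only
        ld = pd.DataFrame(columns=["chrom", "posA", "posB", "r2"])
        feats = svs.build_ld_features(sv, snps, ld)
        assert feats.empty
        assert feats.attrs["n_dropped"] == 1

    def test_flank_distance_limit(self):
        sv = _sv_df([("chr1", 50_000, "DEL", 100)])
        snps = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [44_000, 56_000]})
        ld = pd.DataFrame({"chrom": ["chr1"], "posA": [44_000], "posB": [56_000],
                           "r2": [0.3]})
        feats = svs.build_ld_features(sv, snps, ld, flank=5_000)
        assert feats.empty  # both flanks beyond 5 kb

    def test_shared_pair_flagged(self):
        sv = _sv_df([("chr1", 1_200, "DEL", 100), ("chr1", 1_500, "DEL", 100)])
        snps = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [1_000, 2_000]})
        ld = pd.DataFrame({"chrom": ["chr1"], "posA": [1_000], "posB": [2_000],
                           "r2": [0.4]})
        feats = svs.build_ld_features(sv, snps, ld)
        assert len(feats) == 2
        assert feats["shared_pair"].all()


class TestLdModel:
    @staticmethod
    def _features(rng, n=300, inv_shift=0.0, n_chrom=4, chrom_sd=0.0):
        chrom = rng.choice([f"chr{i}" for i in range(1, n_chrom + 1)], size=n)
        svtype = rng.choice(["DEL", "INS", "INV"], size=n, p=[0.4, 0.4, 0.2])
        prop = rng.uniform(0, 1, size=n)
        dist = rng.uniform(0, 1e-4, size=n)
        u = {f"chr{i}": rng.normal(0, chrom_sd) for i in range(1, n_chrom + 1)}
        r2 = (0.05 + 0.1 * prop + np.where(svtype == "INV", inv_shift, 0.0)
              + np.array([u[c] for c in chrom]) + rng.normal(0, 0.05, size=n))
        return pd.DataFrame({"chrom": chrom, "svtype": svtype, "r2": r2,
                             "prop_covered": prop, "inv_freq_dist": dist})

    def test_zero_type_effect_contrasts_insignificant(self, rng):
        sig = 0
        for _ in range(5):
            res = svs.fit_ld_model(self._features(rng))
            if res.contrasts["DEL_vs_INV"]["p"] < 0.05:
                sig += 1
        assert sig <= 1

    def test_zero_random_variance_estimated_near_zero(self, rng):
        res = svs.fit_ld_model(self._features(rng, n=500, chrom_sd=0.0))
        assert res.chrom_var < 1e-3

    def test_single_chromosome_falls_back_to_ols(self, rng):
        feats = self._features(rng, n_chrom=1)
        with pytest.warns(UserWarning, match="single chromosome"):
            res = svs.fit_ld_model(feats)
        assert res.method == "ols"

    def test_ols_route_matches_lstsq_oracle(self, rng):
        feats = self._features(rng, n=200, n_chrom=1)
        with pytest.warns(UserWarning):
            res = svs.fit_ld_model(feats)
        # rebuild the design exactly as the model does and solve directly
        d = feats.copy()
        for col, src in (("dist_s", "inv_freq_dist"), ("prop_s", "prop_covered")):
            x = d[src].to_numpy(float)
            d[col] = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack([
            np.ones(len(d)),
            (d["svtype"] == "INS").astype(float),
            (d["svtype"] == "INV").astype(float),
            d["dist_s"], d["prop_s"],
        ])
        beta, *_ = np.linalg.lstsq(X, d["r2"].to_numpy(), rcond=None)
        assert res.fixed["Intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert res.fixed["dist_s"] == pytest.approx(beta[3], abs=1e-8)
        assert res.fixed["prop_s"] == pytest.approx(beta[4], abs=1e-8)

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError):
            svs.fit_ld_model(self._features(rng, n=5))


class TestSpotEnrichment:
    LAYOUT = GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})

    def test_whole_genome_regions_ratio_one(self, rng):
        df = _sv_df([("chr1", int(p), "DEL", 50)
                     for p in rng.choice(999_000, 50, replace=False)])
        res = svs.spot_enrichment(
            df, regions(("chr1", 0, 1_000_000)), self.LAYOUT, 200, rng)
        assert res.ratio == pytest.approx(1.0)
        assert res.p == 1.0

    def test_planted_maximum(self, rng):
        df = _sv_df([("chr1", 10_000 + i * 10, "DEL", 5) for i in range(50)])
        res = svs.spot_enrichment(
            df, regions(("chr1", 9_000, 12_000)), self.LAYOUT, 500, rng)
        assert res.observed == 50
        assert res.p <= 1 / 500 + 1e-12
        assert res.ratio > 5

    def test_region_longer_than_chromosome_rejected(self, rng):
        df = _sv_df([("chr1", 100, "DEL", 50)])
        layout = GenomeLayout({"chr1": 1_000})
        with pytest.raises(ValueError):
            svs.spot_enrichment(df, regions(("chr1", 0, 900)),
                                GenomeLayout({"chr1": 500}), 10, rng)

    def test_invariant_to_order_preserving_relabeling(self, rng):
        df = _sv_df([("chr1", int(p), "DEL", 50)
                     for p in rng.choice(900_000, 40, replace=False)]
                    + [("chr2", int(p), "INS", 50)
                       for p in rng.choice(900_000, 40, replace=False)])
        reg = regions(("chr1", 100_000, 150_000), ("chr2", 300_000, 380_000))
        r1 = svs.spot_enrichment(df, reg, self.LAYOUT, 300,
                                 np.random.default_rng(9))
        relabel = {"chr1": "chrA", "chr2": "chrB"}
        df2 = df.assign(chrom=df["chrom"].map(relabel))
        reg2 = RegionSet(reg.df.assign(chrom=reg.df["chrom"].map(relabel)))
        layout2 = GenomeLayout({"chrA": 1_000_000, "chrB": 1_000_000})
        r2 = svs.spot_enrichment(df2, reg2, layout2, 300,
                                 np.random.default_rng(9))
        assert r1.observed == r2.observed
        assert r1.p == r2.p
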