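"""Weir-Cockerham F_ST, recombination bins, window enrichment, overlap tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recdiff import diffscan
from recdiff.intervals import BinnedTrack, GenomeLayout, RegionSet
from conftest import regions
import _oracles


def _random_count_configs(rng, n):
    """Random genotype-count configurations with both pops polymorphic-capable."""
    out = []
    while len(out) < n:
        n1, n2 = rng.integers(2, 60, size=2)
        g1 = rng.multinomial(n1, rng.dirichlet([1, 1, 1]))
        g2 = rng.multinomial(n2, rng.dirichlet([1, 1, 1]))
        ac1, het1 = g1[1] + 2 * g1[2], g1[1]
        ac2, het2 = g2[1] + 2 * g2[2], g2[1]
        if (ac1 + ac2 == 0) or (ac1 + ac2 == 2 * (n1 + n2)):
            continue  # monomorphic overall: theta undefined
        out.append((int(n1), int(ac1), int(het1), int(n2), int(ac2), int(het2)))
    return out


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        theta = diffscan.wc_fst(20, 40, 0, 20, 0, 0)
        assert theta == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self, rng):
        vals = []
        for _ in range(300):
            p = rng.uniform(0.2, 0.8)
            g1 = rng.binomial(2, p, size=100)
            g2 = rng.binomial(2, p, size=100)
            vals.append(
                diffscan.wc_fst(100, g1.sum(), (g1 == 1).sum(),
                                100, g2.sum(), (g2 == 1).sum())
            )
        assert np.mean(np.abs(vals)) < 0.05

    def test_monomorphic_missing(self):
        assert np.isnan(diffscan.wc_fst(10, 0, 0, 12, 0, 0))

    def test_matches_independent_variance_component_oracle(self, rng):
        for cfg in _random_count_configs(rng, 1000):
            ours = diffscan.wc_fst(*cfg)
            oracle = _oracles.wc_theta(*cfg)
            assert ours == pytest.approx(oracle, abs=1e-12)


class TestAssignBins:
    def test_uniform_values_balanced_counts(self, rng):
        labels, _ = diffscan.assign_bins(rng.uniform(size=1000))
        counts = np.bincount(labels)[1:]
        assert counts.max() - counts.min() <= 1

    def test_degenerate_ties_warn(self):
        with pytest.warns(UserWarning, match="tied"):
            labels, _ = diffscan.assign_bins(np.ones(50))
        assert set(labels) <= {1, 2, 3, 4, 5}

    def test_edges_match_sort_based_oracle(self):
        vals = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 9.3])
        _, edges = diffscan.assign_bins(vals)
        expected = np.percentile(vals, [20, 40, 60, 80])
        assert np.allclose(edges, expected)

    def test_nan_unbinned(self):
        labels, _ = diffscan.assign_bins(np.array([1.0, np.nan, 2.0, 3.0, 4.0,
                                                   5.0]))
        assert labels[1] == 0 and (labels[[0, 2, 3, 4, 5]] > 0).all()


def _snp_frame(rng, n=5000, n_bins=5):
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.sort(rng.choice(10_000_000, n, replace=False)),
            "fst": rng.normal(0.02, 0.02, size=n),
        }
    )
    df["win_start"] = (df["pos"] // 100_000) * 100_000
    df["bin"] = rng.integers(1, n_bins + 1, size=n)
    return df


class TestBinwiseOutliers:
    def test_about_one_percent_flagged_per_bin(self, rng):
        df = diffscan.binwise_outliers(_snp_frame(rng))
        for _, sub in df.groupby("bin"):
            assert abs(sub["outlier"].mean() - 0.01) < 0.01

    def test_bins_independent(self, rng):
        df = _snp_frame(rng)
        flagged = diffscan.binwise_outliers(df)
        shifted = df.copy()
        shifted.loc[shifted["bin"] == 3, "fst"] += 0.5
        flagged_shift = diffscan.binwise_outliers(shifted)
        other = df["bin"] != 3
        assert (
            flagged.loc[other, "outlier"].to_numpy()
            == flagged_shift.loc[other, "outlier"].to_numpy()
        ).all()


class TestWindowEnrichment:
    @staticmethod
    def _scan_from_counts(counts, p0_target=None):
        """Build a SNP frame realizing given (n, k) per window."""
        rows = []
        pos = 0
        for w, (n, k) in enumerate(counts):
            for i in range(n):
                rows.append(("chr1", w * 100_000 + i * 10 + 1, 1,
                             w * 100_000, 0.5 if i < k else 0.0, i < k))
            pos += 1
        df = pd.DataFrame(rows, columns=["chrom", "pos", "bin", "win_start",
                                         "fst", "outlier"])
        return diffscan.window_enrichment(df)

    def test_zero_outliers_give_p_one(self):
        scan = self._scan_from_counts([(50, 0), (60, 0), (55, 3)])
        assert scan.windows.loc[scan.windows["n_outliers"] == 0, "p"].tolist() == \
            pytest.approx([1.0, 1.0])

    def test_matches_term_by_term_oracle(self):
        # windows engineered so that p0 = 0.01 exactly: 500 SNPs, 5 outliers
        counts = [(100, 5)] + [(100, 0)] * 4
        scan = self._scan_from_counts(counts)
        assert scan.p0 == pytest.approx(0.01)
        p = scan.windows.loc[scan.windows["n_outliers"] == 5, "p"].iloc[0]
        assert p == pytest.approx(_oracles.binom_upper_tail(5, 100, 0.01),
                                  rel=1e-12)
        assert p == pytest.approx(3.4323e-3, rel=1e-3)

    def test_small_windows_filtered(self):
        scan = self._scan_from_counts([(9, 2), (50, 0), (50, 1)])
        assert len(scan.windows) == 2

    def test_p_monotone_in_k(self):
        ps = []
        for k in range(0, 6):
            scan = self._scan_from_counts([(100, k)] + [(100, 2)] * 9)
            row = scan.windows.iloc[0]
            ps.append(row["p"])
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_adjacent_enriched_windows_merged(self):
        counts = [(100, 20), (100, 20), (100, 0), (100, 0), (100, 20)]
        scan = self._scan_from_counts(counts)
        assert scan.n_enriched == 3
        assert scan.n_enriched_merged == 2
        assert scan.merged.df.iloc[0][["start", "end"]].tolist() == [0, 200_000]


class TestPearsonChi2:
    def test_matches_scipy_without_correction(self, rng):
        for _ in range(50):
            t = rng.integers(1, 50, size=(2, 2))
            ours = diffscan.pearson_chi2(t)
            ref = stats.chi2_contingency(t, correction=False)[0]
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_degenerate_margin_gives_zero(self):
        assert diffscan.pearson_chi2(np.array([[5, 0], [7, 0]])) == 0.0


class TestRepeatedOverlap:
    def test_whole_genome_candidates_degenerate(self, layout2, rng):
        windows = regions(*[("chr1", s, s + 100_000)
                            for s in range(0, 2_000_000, 100_000)])
        enriched = RegionSet(windows.df.iloc[:5].reset_index(drop=True))
        background = RegionSet(windows.df.iloc[5:].reset_index(drop=True))
        genome = regions(("chr1", 0, 10_000_000), ("chr2", 0, 10_000_000))
        res = diffscan.repeated_overlap_test(enriched, background, genome,
                                             layout2, n_perm=50, rng=rng)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_planted_maximum_overlap(self, layout2, rng):
        enriched = regions(*[("chr1", s, s + 100_000)
                             for s in range(0, 1_000_000, 100_000)])
        background = regions(*[("chr2", s, s + 100_000)
                               for s in range(0, 8_000_000, 100_000)])
        candidates = regions(("chr1", 0, 1_000_000))
        res = diffscan.repeated_overlap_test(enriched, background, candidates,
                                             layout2, n_perm=100, rng=rng)
        assert res.n_ge == 0
        assert res.p_label == "< 0.01"

    def test_empty_candidates_rejected(self, layout2, rng):
        enriched = regions(("chr1", 0, 100_000))
        with pytest.raises(ValueError):
            diffscan.repeated_overlap_test(enriched, enriched,
                                           RegionSet.empty(), layout2, 10, rng)


class TestOverlapPercentages:
    def test_study_percentages(self):
        enriched = regions(*[("chr1", i * 200_000, i * 200_000 + 100_000)
                             for i in range(1037)])
        # 71 candidate hits: overlap the first 71 enriched windows
        cand_rows = [("chr1", i * 200_000 + 50_000, i * 200_000 + 150_000)
                     for i in range(71)]
        candidates = regions(*cand_rows)
        out = diffscan.overlap_percentages(enriched, candidates)
        assert out["n_enriched_overlapping"] == 71
        assert out["pct_enriched_overlapping"] == 6.85
        assert out["pct_candidates_hit"] == 100.0

    def test_disjoint_zero(self):
        out = diffscan.overlap_percentages(regions(("chr1", 0, 10)),
                                           regions(("chr1", 20, 30)))
        assert out["pct_enriched_overlapping"] == 0.0

    def test_subset_is_total(self):
        enriched = regions(("chr1", 10, 20), ("chr1", 40, 50))
        candidates = regions(("chr1", 0, 100))
        out = diffscan.overlap_percentages(enriched, candidates)
        assert out["pct_enriched_overlapping"] == 100.0
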