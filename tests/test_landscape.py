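"""PRDI, Δr, and hotspot/coldspot calling."""

import math

import numpy as np
import pandas as pd
import pytest

from recdiff import landscape, simulate
from recdiff.intervals import BinnedTrack, GenomeLayout, RegionSet, bin_average
from conftest import regions
import _oracles


def _track(values, chrom="chr1", width=2000):
    n = len(values)
    return BinnedTrack(
        pd.DataFrame(
            {"chrom": chrom, "start": np.arange(n) * width,
             "end": (np.arange(n) + 1) * width, "value": values}
        ),
        width,
    )


def _two_pop_tracks(values_by_key):
    return {key: _track(vals) for key, vals in values_by_key.items()}


class TestWindowSpearman:
    def test_identical_tracks_give_rho_one(self, rng):
        v = rng.lognormal(size=100)
        tracks = _two_pop_tracks(
            {("pop1", 0): v, ("pop1", 1): v, ("pop2", 0): v, ("pop2", 1): v}
        )
        panel = landscape.window_spearman(tracks, window=200_000)
        assert np.allclose(panel["rho"], 1.0)

    def test_monotone_transform_invariance(self, rng):
        v = rng.lognormal(size=100)
        tracks = _two_pop_tracks(
            {("pop1", 0): v, ("pop1", 1): np.exp(v), ("pop2", 0): v ** 3,
             ("pop2", 1): 5 * v + 1}
        )
        panel = landscape.window_spearman(tracks, window=200_000)
        assert np.allclose(panel["rho"], 1.0)

    def test_matches_brute_force_rank_formula(self, rng):
        a = list(rng.normal(size=12))
        b = list(rng.normal(size=12))
        tracks = _two_pop_tracks(
            {("pop1", 0): a, ("pop1", 1): a, ("pop2", 0): b, ("pop2", 1): b}
        )
        panel = landscape.window_spearman(tracks, window=24_000, min_bins=5)
        between = panel[panel["kind"] == "between"]["rho"].iloc[0]
        assert between == pytest.approx(_oracles.spearman_rho(a, b), abs=1e-12)

    def test_too_few_paired_bins_gives_nan(self):
        a = [1.0, 2.0, np.nan, np.nan, np.nan, np.nan]
        b = [2.0, 1.0, 3.0, 4.0, 5.0, 6.0]
        tracks = _two_pop_tracks(
            {("pop1", 0): a, ("pop1", 1): a, ("pop2", 0): b, ("pop2", 1): b}
        )
        panel = landscape.window_spearman(tracks, window=12_000, min_bins=5)
        assert panel[panel["kind"] == "between"]["rho"].isna().all()


class TestMeAndPrdi:
    @staticmethod
    def _panel(w1, w2, bt):
        rows = []
        for kind, vals in (("within_pop1", w1), ("within_pop2", w2),
                           ("between", bt)):
            for i, v in enumerate(vals):
                rows.append(("chr1", 0, kind, f"a{i}", f"b{i}", v, 50))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "kind", "rep_a", "rep_b", "rho",
                           "n_bins"]
        )

    def test_all_equal_correlations_give_zero(self):
        panel = self._panel([0.9, 0.9], [0.9], [0.9, 0.9])
        assert landscape.compute_me(panel) == pytest.approx(0.0)

    def test_study_style_medians(self):
        # within medians 0.90 / 0.93, between 0.86 -> me = 0.04
        panel = self._panel([0.90], [0.93], [0.86])
        assert landscape.compute_me(panel) == pytest.approx(0.04)

    def test_hand_built_panel(self):
        panel = self._panel([0.8, 0.9, 1.0], [0.7, 0.95], [0.6, 0.62, 0.64])
        # min(median within) = min(0.9, 0.825) = 0.825; between median 0.62
        assert landscape.compute_me(panel) == pytest.approx(0.825 - 0.62)

    def test_empty_group_rejected(self):
        panel = self._panel([0.9], [0.9], [])
        with pytest.raises(ValueError):
            landscape.compute_me(panel)

    def test_prdi_zero_when_me_equals_ms(self):
        assert landscape.compute_prdi(0.12, 0.12).prdi == pytest.approx(0.0)

    def test_profile_matches_per_window_contrast(self):
        emp = self._panel([0.9], [0.9], [0.7])
        neu = self._panel([0.9], [0.9], [0.88])
        prof = landscape.prdi_profile(emp, neu)
        assert prof["prdi"].iloc[0] == pytest.approx((0.9 - 0.7) - (0.9 - 0.88))


class TestDeltaR:
    def test_identical_tracks_hit_epsilon_floor(self, rng):
        v = rng.lognormal(size=50)
        df = landscape.delta_r(_track(v), _track(v), window=100_000, eps=1e-12)
        assert df["dr"].tolist() == pytest.approx([math.log(1e-12)])

    def test_constant_offset_closed_form(self, rng):
        v = rng.lognormal(size=100)
        delta = 3.5e-9
        df = landscape.delta_r(_track(v), _track(v + delta), window=100_000)
        assert np.allclose(df["dr"], math.log(delta + 1e-12))

    def test_hand_summed_manhattan_distance(self, rng):
        a = rng.lognormal(size=50)
        b = rng.lognormal(size=50)
        df = landscape.delta_r(_track(a), _track(b), window=100_000)
        hand = math.log(sum(abs(x - y) for x, y in zip(a, b)) / 50 + 1e-12)
        assert df["dr"].iloc[0] == pytest.approx(hand, rel=1e-12)

    def test_window_with_missing_bin_dropped(self, rng):
        a = rng.lognormal(size=100)
        b = a.copy()
        a[10] = np.nan
        df = landscape.delta_r(_track(a), _track(b), window=100_000)
        assert df["start"].tolist() == [100_000]

    def test_extreme_window_flagged(self, rng):
        rows = []
        n_win = 40
        for i in range(n_win):
            w = rng.normal(-20, 0.1)
            b = rng.normal(-20, 0.1)
            rows.append(("chr1", i * 100_000, w, b + (10 if i == 7 else 0)))
        meds = pd.DataFrame(rows, columns=["chrom", "start", "dr_within",
                                           "dr_between"])
        outliers, table = landscape.delta_r_outliers(meds)
        assert table["outlier"].sum() == 1
        assert outliers.df["start"].tolist() == [700_000]

    def test_recovers_planted_divergent_segments(self, layout2):
        seg = [("chr1", 2_000_000, 3_000_000, 2.0)]
        p = simulate.LandscapeParams(layout=layout2, n_replicates=3,
                                     divergence_segments=seg, seed=21)
        ls = simulate.simulate_landscapes(p)
        tracks = {k: bin_average(m, 2000, layout2) for k, m in ls.maps.items()}
        meds = landscape.delta_r_medians(tracks)
        outliers, table = landscape.delta_r_outliers(meds)
        flagged = set(zip(outliers.df["chrom"], outliers.df["start"]))
        planted = {("chr1", s) for s in range(2_000_000, 3_000_000, 100_000)}
        assert flagged  # divergence found
        assert flagged <= planted  # and only inside the planted segment


class TestCallSpots:
    def test_constant_track_no_calls(self):
        calls = landscape.call_spots(_track(np.full(200, 1e-8)))
        assert calls.n == 0

    def test_single_spike_on_flat_background(self):
        v = np.full(200, 1e-8)
        v[100] = 1e-8 * math.exp(4.0)
        calls = landscape.call_spots(_track(v))
        assert calls.n == 1
        assert calls.df.iloc[0]["name"] == "hotspot"
        assert calls.df.iloc[0]["end"] - calls.df.iloc[0]["start"] == 2000

    def test_long_hotspot_removed_by_length_cap(self, rng):
        logv = rng.normal(0, 0.1, size=300)
        logv[100:104] += 8.0  # four 2 kb bins = 8 kb elevated region
        calls = landscape.call_spots(_track(np.exp(logv) * 1e-8))
        hot = calls.df[calls.df["name"] == "hotspot"]
        assert not ((hot["start"] <= 206_000) & (hot["end"] >= 200_000)).any()

    def test_coldspot_called_below_background(self, rng):
        logv = rng.normal(0, 0.1, size=300)
        logv[150] -= 4.0
        calls = landscape.call_spots(_track(np.exp(logv) * 1e-8))
        cold = calls.df[calls.df["name"] == "coldspot"]
        assert ((cold["start"] <= 300_000) & (cold["end"] > 300_000)).any()

    def test_zero_rates_floored_not_fatal(self, rng):
        v = np.exp(rng.normal(0, 0.1, size=300)) * 1e-8
        v[50] = 0.0
        calls = landscape.call_spots(_track(v))
        cold = calls.df[calls.df["name"] == "coldspot"]
        assert ((cold["start"] <= 100_000) & (cold["end"] > 100_000)).any()


class TestSharing:
    @staticmethod
    def _sets(n_a, n_b, shared):
        rows_a, rows_b = [], []
        pos = 0
        for _ in range(shared):
            rows_a.append(("chr1", pos, pos + 1000))
            rows_b.append(("chr1", pos + 500, pos + 1500))
            pos += 10_000
        for _ in range(n_a - shared):
            rows_a.append(("chr1", pos, pos + 1000))
            pos += 10_000
        for _ in range(n_b - shared):
            rows_b.append(("chr1", pos, pos + 1000))
            pos += 10_000
        return regions(*rows_a), regions(*rows_b)

    def test_study_hotspot_counts(self):
        a, b = self._sets(105, 188, 58)
        s = landscape.sharing_summary(a, b)
        assert s["shared"] == 58
        assert s["pct_of_a"] == 55
        assert s["pct_of_b"] == 31

    def test_study_coldspot_counts(self):
        a, b = self._sets(208, 429, 98)
        s = landscape.sharing_summary(a, b)
        assert s["pct_of_a"] == 47
        assert s["pct_of_b"] == 23

    def test_disjoint_sets_share_nothing(self):
        a, b = self._sets(5, 7, 0)
        s = landscape.sharing_summary(a, b)
        assert s["shared"] == 0 and s["pct_of_a"] == 0 and s["pct_of_union"] == 0

    def test_self_sharing_is_total(self):
        a, _ = self._sets(6, 1, 0)
        s = landscape.sharing_summary(a, a)
        assert s["shared"] == 6 and s["pct_of_a"] == 100
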