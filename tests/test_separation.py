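"""Pattern-separation statistics against hand and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from dgsep.backend import SimulationResult
from dgsep.separation import (RateVector, SimilarityPair, activity_metrics,
                              all_pairs, band_mean, binwise_curve, cov_delta,
                              isolated_effect, mean_delta_rout_full,
                              rate_vector, similarity, time_resolved,
                              time_windows)

try:
    from hypothesis import given, settings, strategies as st
    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def mkpairs(r_in, r_out):
    return [SimilarityPair(p=i, q=i + 1, r_in=a, r_out=b)
            for i, (a, b) in enumerate(zip(r_in, r_out))]


class TestRateVector:
    def test_counts_to_hz(self):
        spikes = [np.array([10.0, 200.0, 550.0]), np.empty(0)]
        rv = rate_vector(spikes, (0.0, 600.0))
        np.testing.assert_allclose(rv.values, [5.0, 0.0])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            rate_vector([np.empty(0)], (100.0, 100.0))

    def test_windowed_rates_average_to_full_rate(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(0, 600.0, rng.integers(0, 20)))
                  for _ in range(50)]
        full = rate_vector(spikes, (0.0, 600.0)).values
        wins = [rate_vector(spikes, w).values for w in time_windows(600.0, 100.0)]
        np.testing.assert_allclose(np.mean(wins, axis=0), full, atol=1e-12)


class TestSimilarity:
    def test_identical_vectors_all_measures(self):
        v = np.array([1.0, 2.0, 0.0, 3.0])
        for m in ("PEARSON", "NDP", "OVERLAP"):
            assert similarity(v, v, m) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a, b = np.array([1.0, 2.0, 0, 0]), np.array([0, 0, 3.0, 1.0])
        assert similarity(a, b, "OVERLAP") == 0.0
        assert similarity(a, b, "NDP") == 0.0

    def test_hand_oracle_values(self):
        """Brute-force arithmetic oracle for a=(1,2,0,0), b=(0,2,1,0):
        OVERLAP = 1 coactive / 3 active = 1/3; NDP = 4/sqrt(5*5) = 4/5;
        PEARSON = cov/sd^2 = 0.4375/0.6875 = 7/11 (cross-checked with
        scipy.stats.pearsonr)."""
        a, b = np.array([1.0, 2, 0, 0]), np.array([0.0, 2, 1, 0])
        assert similarity(a, b, "OVERLAP") == pytest.approx(1 / 3)
        assert similarity(a, b, "NDP") == pytest.approx(4 / 5)
        assert similarity(a, b, "PEARSON") == pytest.approx(7 / 11)
        assert similarity(a, b, "PEARSON") == pytest.approx(
            stats.pearsonr(a, b).statistic)

    def test_undefined_cases_flagged_nan(self):
        z = np.zeros(4)
        assert np.isnan(similarity(z, np.array([1.0, 2, 3, 4]), "NDP"))
        assert np.isnan(similarity(np.ones(4), np.array([1.0, 2, 3, 4]),
                                   "PEARSON"))

    if HAVE_HYPOTHESIS:
        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.integers(0, 2**31 - 1), st.sampled_from(["PEARSON", "NDP",
                                                           "OVERLAP"]))
        def test_symmetry_and_bounds(self, seed, measure):
            rng = np.random.default_rng(seed)
            a = np.round(rng.exponential(2.0, 30) * (rng.random(30) < 0.5), 2)
            b = np.round(rng.exponential(2.0, 30) * (rng.random(30) < 0.5), 2)
            r1, r2 = similarity(a, b, measure), similarity(b, a, measure)
            if np.isnan(r1):
                assert np.isnan(r2)
            else:
                assert r1 == pytest.approx(r2)
                lo = -1.0 if measure == "PEARSON" else 0.0
                assert lo - 1e-12 <= r1 <= 1.0 + 1e-12


class TestAllPairs:
    def make_vecs(self, n):
        rng = np.random.default_rng(1)
        return [RateVector(rng.random(20)) for _ in range(n)]

    def test_pair_counts(self):
        vi, vo = self.make_vecs(25), self.make_vecs(25)
        assert len(all_pairs(vi, vo, with_self=True)) == 325
        assert len(all_pairs(vi, vo, with_self=False)) == 300
        assert len(all_pairs(vi[:2], vo[:2], with_self=False)) == 1

    def test_self_pairs_have_unit_similarity(self):
        vi, vo = self.make_vecs(3), self.make_vecs(3)
        pairs = all_pairs(vi, vo, with_self=True)
        for p in pairs:
            if p.p == p.q:
                assert p.r_in == pytest.approx(1.0)
                assert p.r_out == pytest.approx(1.0)


class TestBinwiseCurve:
    def test_unity_mapping_lies_on_unity_line(self):
        r = np.linspace(0.05, 0.95, 50)
        s = binwise_curve(mkpairs(r, r))
        occ = s.occupied
        np.testing.assert_allclose(s.bin_mean_rin[occ], s.bin_mean_rout[occ])
        assert mean_delta_rout_full(s) == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_occupies_one_bin(self):
        s = binwise_curve(mkpairs([0.35], [0.2]))
        assert s.bin_count.sum() == 1
        assert s.bin_count[3] == 1

    def test_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(5)
        r_in = rng.random(500)
        r_out = rng.random(500)
        s = binwise_curve(mkpairs(r_in, r_out))
        k = np.minimum((r_in * 10).astype(int), 9)
        for b in range(10):
            sel = k == b
            if sel.any():
                assert s.bin_mean_rin[b] == pytest.approx(r_in[sel].mean())
                assert s.bin_mean_rout[b] == pytest.approx(r_out[sel].mean())
            else:
                assert np.isnan(s.bin_mean_rout[b])

    def test_rin_one_goes_to_top_bin(self):
        s = binwise_curve(mkpairs([1.0], [0.9]))
        assert s.bin_count[9] == 1


class TestMeanDelta:
    def test_zero_output_correlation(self):
        r_in = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75,
                         0.85, 0.95])
        s = binwise_curve(mkpairs(r_in, np.zeros(10)))
        assert mean_delta_rout_full(s) == pytest.approx(0.5)

    def test_half_output_correlation(self):
        r_in = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75,
                         0.85, 0.95])
        s = binwise_curve(mkpairs(r_in, r_in / 2))
        assert mean_delta_rout_full(s) == pytest.approx(np.mean(r_in / 2))


class TestIsolatedEffect:
    def test_identity_gives_zero(self):
        a = mkpairs(np.linspace(0.1, 0.9, 20), np.linspace(0.1, 0.9, 20) ** 2)
        eff = isolated_effect(a, a)
        assert mean_delta_rout_full(eff) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_recovered(self):
        r = np.linspace(0.05, 0.95, 40)
        a = mkpairs(r, r - 0.2)
        b = mkpairs(r, r - 0.1)   # B has 0.1 higher R_out everywhere
        eff = isolated_effect(a, b)
        assert mean_delta_rout_full(eff) == pytest.approx(0.1)
        assert band_mean(eff, 0.9, 1.0) == pytest.approx(0.1)

    def test_subtract_then_average_equals_average_then_subtract(self):
        rng = np.random.default_rng(9)
        r = rng.random(300)
        a = mkpairs(r, np.clip(r - rng.random(300) * 0.2, 0, 1))
        b = mkpairs(r, np.clip(r - rng.random(300) * 0.1, 0, 1))
        eff = isolated_effect(a, b)
        ca, cb = binwise_curve(a), binwise_curve(b)
        occ = eff.occupied
        np.testing.assert_allclose(eff.bin_mean_rout[occ],
                                   cb.bin_mean_rout[occ] - ca.bin_mean_rout[occ],
                                   atol=1e-12)

    def test_unmatched_pairs_rejected(self):
        a = mkpairs([0.5, 0.6], [0.4, 0.5])
        b = mkpairs([0.5], [0.45])
        with pytest.raises(ValueError, match="missing"):
            isolated_effect(a, b)


class TestCov:
    def test_constant_delta_zero_cov(self):
        r = np.linspace(0.25, 0.75, 40)
        a = mkpairs(r, r)
        b = mkpairs(r, r + 0.1)
        assert cov_delta(isolated_effect(a, b)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cov(self):
        # one usable bin [0.3, 0.4) holding deltas {1, 3}: SD/mean = sqrt(2)/2
        r_in = np.array([0.35, 0.36])
        delta = np.array([1.0, 3.0])
        assert cov_delta((r_in, delta)) == pytest.approx(np.sqrt(2) / 2)

    def test_border_bins_excluded(self):
        r_in = np.array([0.05, 0.95, 0.35, 0.36])   # outliers in border bins
        delta = np.array([100.0, -100.0, 1.0, 3.0])
        assert cov_delta((r_in, delta)) == pytest.approx(np.sqrt(2) / 2)


class TestTimeResolved:
    def fake_results(self, n=4):
        rng = np.random.default_rng(2)
        res = []
        for _ in range(n):
            spikes = [np.sort(rng.uniform(0, 600.0, rng.integers(0, 15)))
                      for _ in range(40)]
            res.append(SimulationResult(spikes={"GC": spikes}, duration=600.0,
                                        dt=0.1, condition="FULL"))
        return res

    def test_window_partition(self):
        assert len(time_windows(600.0, 100.0)) == 6
        assert time_windows(600.0, 600.0) == [(0.0, 600.0)]
        with pytest.raises(ValueError):
            time_windows(600.0, 700.0)
        with pytest.warns(UserWarning, match="partial"):
            assert len(time_windows(600.0, 250.0)) == 2

    def test_full_window_reduces_to_600ms_analysis(self, short_family,
                                                   desk_results):
        series = time_resolved(short_family, desk_results, 300.0)
        pairs = __import__("dgsep").pairs_from_results(
            short_family, desk_results, window=(0.0, 300.0))
        ref = binwise_curve(pairs)
        occ = series[0].occupied
        np.testing.assert_allclose(series[0].bin_mean_rout[occ],
                                   ref.bin_mean_rout[occ])


class TestActivityMetrics:
    def test_hand_counted_toy_raster(self):
        spikes = {"GC": [np.array([1.0]), np.empty(0), np.array([2.0, 3.0]),
                         np.empty(0)],
                  "BC": [np.array([1.0, 2.0])]}
        res = SimulationResult(spikes=spikes, duration=100.0, dt=0.1,
                               condition="FULL")
        m = activity_metrics(res)
        assert m["active_fraction"] == pytest.approx(0.5)
        assert m["mean_rate_active"] == pytest.approx((10.0 + 20.0) / 2)
        assert m["interneuron_rates"]["BC"] == pytest.approx(20.0)

    def test_no_spikes_zero_fraction(self):
        res = SimulationResult(spikes={"GC": [np.empty(0)] * 5}, duration=100.0,
                               dt=0.1, condition="FULL")
        assert activity_metrics(res)["active_fraction"] == 0.0
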