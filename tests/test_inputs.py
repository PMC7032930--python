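"""Oscillation-modulated Poisson inputs and pattern-family structure."""

import numpy as np
import pytest
from scipy import stats

import dgsep
from dgsep import (InputConfig, connect_pp, generate_pattern_family,
                   inhomogeneous_poisson, rate_profile)
from dgsep.config import ConfigurationError


class TestRateProfile:
    def test_theta_profile_cycles_and_range(self):
        r = rate_profile(10.0, 100.0, 0.0, 600.0)
        t = np.linspace(0.0, 600.0, 60001)
        v = r(t)
        assert v.min() == pytest.approx(0.0, abs=1e-9)
        assert v.max() == pytest.approx(100.0)
        assert r(0.0) == pytest.approx(0.0, abs=1e-12)   # starts at the trough
        upward = np.count_nonzero((v[:-1] < 50.0) & (v[1:] >= 50.0))
        assert upward == 6                                # 6 full theta cycles

    def test_time_average_is_midpoint(self):
        r = rate_profile(10.0, 100.0, 0.0, 600.0)
        t = np.linspace(0.0, 600.0, 600001)
        assert np.trapezoid(r(t), t) / 600.0 == pytest.approx(50.0, rel=1e-6)

    def test_degenerate_constant_profile(self):
        r = rate_profile(10.0, 40.0, 40.0, 600.0)
        np.testing.assert_allclose(r(np.linspace(0, 600, 101)), 40.0)

    def test_peak_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            rate_profile(10.0, 10.0, 50.0)


class TestInhomogeneousPoisson:
    def test_zero_rate_empty_train(self):
        assert len(inhomogeneous_poisson(0.0, 600.0, seed=1)) == 0

    def test_theta_profile_mean_count(self):
        """Mean count equals the rate integral: 50 Hz x 0.6 s = 30."""
        r = rate_profile(10.0, 100.0, 0.0, 600.0)
        rng = np.random.default_rng(123)
        counts = [len(inhomogeneous_poisson(r, 600.0, seed=rng))
                  for _ in range(400)]
        sem = np.std(counts) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(30.0, abs=4 * sem + 0.5)

    def test_constant_rate_count_distribution_poisson(self):
        """Counts for 100 Hz x 600 ms follow Poisson(60) (chi-square, a=0.01)."""
        rng = np.random.default_rng(7)
        counts = np.array([len(inhomogeneous_poisson(100.0, 600.0, seed=rng))
                           for _ in range(600)])
        lo, hi = 40, 82
        edges = np.arange(lo, hi, 6)
        obs, _ = np.histogram(np.clip(counts, lo, hi - 1), bins=edges)
        cdf = stats.poisson(60.0).cdf
        probs = []
        for a, b in zip(edges[:-1], edges[1:]):
            pa = cdf(a - 1) if a > lo else 0.0
            pb = cdf(b - 1) if b < hi - 1 else 1.0
            probs.append(pb - pa)
        exp = np.array(probs) * len(counts)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2(len(obs) - 1).ppf(0.99)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inhomogeneous_poisson(lambda t: -np.ones_like(t), 100.0, seed=0,
                                  max_rate=10.0)

    def test_deterministic_per_seed(self):
        r = rate_profile(30.0, 100.0, 0.0, 600.0)
        np.testing.assert_array_equal(inhomogeneous_poisson(r, 600.0, seed=5),
                                      inhomogeneous_poisson(r, 600.0, seed=5))


class TestPatternFamily:
    def test_overlap_follows_increment_rule(self):
        cfg = InputConfig()  # 24 of 400, 25 patterns, increment 1
        fam = generate_pattern_family(cfg)
        assert fam.n_patterns == 25
        assert fam.overlap(0, 0) == 24
        assert fam.overlap(0, 12) == 12
        assert fam.overlap(0, 24) == 0
        assert len(np.intersect1d(fam.patterns[0], fam.patterns[24])) == 0
        assert len(np.intersect1d(fam.patterns[0], fam.patterns[12])) == 12

    def test_shared_afferents_carry_identical_trains(self):
        fam = generate_pattern_family(InputConfig(seed_input=3))
        d5, d6 = fam.drive(5), fam.drive(6)
        for a in np.intersect1d(fam.patterns[5], fam.patterns[6]):
            np.testing.assert_array_equal(d5[int(a)], d6[int(a)])

    def test_mean_rate_independent_of_mod_freq(self):
        """Theta and gamma families have equal mean spike counts (constant
        mean input rate), within sampling error."""
        totals = {}
        for freq in (10.0, 30.0):
            n = []
            for seed in range(6):
                fam = generate_pattern_family(InputConfig(mod_freq=freq,
                                                          seed_input=seed))
                n.append(np.mean([len(v) for v in fam.trains.values()]))
            totals[freq] = np.mean(n)
        assert totals[10.0] == pytest.approx(totals[30.0], rel=0.05)
        assert totals[10.0] == pytest.approx(30.0, rel=0.1)

    def test_family_rin_decreases_with_pattern_distance(self):
        from dgsep.separation import rate_vector, similarity
        fam = generate_pattern_family(InputConfig(seed_input=1))
        vecs = [rate_vector(fam.drive(p), (0.0, 600.0)) for p in (0, 6, 12, 24)]
        r = [similarity(vecs[0], v) for v in vecs]
        assert r[0] == pytest.approx(1.0)
        assert r[0] > r[1] > r[2] > r[3]

    def test_index_overflow_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_pattern_family(InputConfig(n_afferents=40))


class TestConnectPP:
    def test_out_degree_and_determinism(self, desk_config):
        net = dgsep.build_network(desk_config, 0)
        e = net.edges["PP->GC"]
        assert np.all(e.out_degree() == desk_config.pp_n_targets)
        # distinct targets per afferent
        for i in (0, 50, 99):
            tgt = e.targets_of(i)
            assert len(np.unique(tgt)) == len(tgt)
        net2 = dgsep.build_network(desk_config, 0)
        np.testing.assert_array_equal(e.targets, net2.edges["PP->GC"].targets)

    def test_flat_gaussian_limit_is_uniform(self, desk_net):
        """With sd >> lamella the target distribution is uniform (KS, a=0.01)."""
        net = connect_pp(desk_net.copy(), n_targets=50, sd=1e9, seed=11)
        pos = net.positions["GC"][net.edges["PP->GC"].targets]
        u = (pos + 2.0) / 2004.0  # positions are a discrete grid in (0, 2000)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_too_many_targets_rejected(self, desk_net):
        with pytest.raises(ConfigurationError):
            connect_pp(desk_net.copy(), n_targets=10_000, seed=0)
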