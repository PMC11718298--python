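"""Closed-form privacy metrics against brute-force and simulation oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reidscale import (
    FrequencyVector,
    InfoParams,
    PYParams,
    correctness_from_frequencies,
    expected_correctness,
    expected_kanon_violations,
    expected_uniqueness,
    kanon_from_frequencies,
    py_from_info,
    sample_crp,
    uniqueness_from_frequencies,
)
from conftest import brute_force_metric

PARAM_GRID = [PYParams(0.0, 1.0), PYParams(0.3, 2.0), PYParams(0.5, 1.0), PYParams(0.9, 0.5)]


class TestFrequencyForms:
    def test_single_set(self):
        fv = FrequencyVector([1.0])
        assert correctness_from_frequencies(fv, 3) == pytest.approx(1.0 / 3.0)
        assert uniqueness_from_frequencies(fv, 5) == 0.0
        assert uniqueness_from_frequencies(fv, 1) == 1.0

    def test_uniform_four_sets(self):
        fv = FrequencyVector(np.full(4, 0.25))
        # (1/2) * 4 * (1 - (3/4)^2) = 0.875
        assert correctness_from_frequencies(fv, 2) == pytest.approx(0.875)

    def test_n_one_is_certain(self):
        for p in ([0.2, 0.3, 0.5], [1.0], np.full(10, 0.1)):
            fv = FrequencyVector(p)
            assert correctness_from_frequencies(fv, 1) == pytest.approx(1.0)
            assert uniqueness_from_frequencies(fv, 1) == pytest.approx(1.0)

    def test_two_even_sets(self):
        fv = FrequencyVector([0.5, 0.5])
        assert uniqueness_from_frequencies(fv, 2) == pytest.approx(0.5)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            FrequencyVector([0.5, 0.2])
        with pytest.raises(ValueError):
            FrequencyVector([0.5, 0.5, -0.0])

    @pytest.mark.parametrize(
        "probs,n",
        [([0.5, 0.5], 4), ([0.2, 0.3, 0.5], 3), (np.full(4, 0.25), 3)],
    )
    def test_against_exhaustive_enumeration(self, probs, n):
        fv = FrequencyVector(probs)
        kappa = brute_force_metric(fv, n, lambda occ: np.sum(occ > 0) / n)
        xi = brute_force_metric(fv, n, lambda occ: np.sum(occ == 1) / n)
        assert correctness_from_frequencies(fv, n) == pytest.approx(kappa, abs=1e-12)
        assert uniqueness_from_frequencies(fv, n) == pytest.approx(xi, abs=1e-12)
        for k in (1, 2, 3):
            vk = brute_force_metric(fv, n, lambda occ: np.sum(occ[(occ > 0) & (occ < k)]) / n)
            assert kanon_from_frequencies(fv, n, k) == pytest.approx(vk, abs=1e-12)

    def test_kanon_reductions(self):
        fv = FrequencyVector([0.1, 0.2, 0.3, 0.4])
        assert kanon_from_frequencies(fv, 10, 1) == 0.0
        assert kanon_from_frequencies(fv, 10, 2) == pytest.approx(
            uniqueness_from_frequencies(fv, 10), abs=1e-12
        )


class TestExpectedForms:
    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_population_of_one(self, params):
        assert expected_correctness(1, params) == pytest.approx(1.0, abs=1e-12)
        assert expected_uniqueness(1, params) == pytest.approx(1.0, abs=1e-12)
        assert expected_kanon_violations(1, 1, params) == 0.0

    def test_dirichlet_pair_collision(self):
        # two draws from DP(alpha=1) collide with probability 1/(alpha+1)
        assert expected_uniqueness(2, PYParams(0.0, 1.0)) == pytest.approx(0.5, abs=1e-12)

    def test_dp_limit_continuity(self):
        # the analytic d->0 limit must join the d>0 branch smoothly
        for alpha in (0.5, 5.0, 500.0):
            lo = expected_correctness(1000, PYParams(1e-7, alpha))
            at = expected_correctness(1000, PYParams(0.0, alpha))
            assert lo == pytest.approx(at, rel=1e-5)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_monotone_in_n_and_k(self, params):
        ns = np.unique(np.round(np.logspace(0, 9, 28))).astype(float)
        kappa = expected_correctness(ns, params)
        xi = expected_uniqueness(ns, params)
        assert np.all(np.diff(kappa) <= 1e-12)
        assert np.all(np.diff(xi) <= 1e-12)
        vks = [expected_kanon_violations(1000, k, params) for k in range(1, 8)]
        assert np.all(np.diff(vks) >= -1e-12)

    def test_kanon_k2_equals_uniqueness(self):
        for params in PARAM_GRID:
            assert expected_kanon_violations(500, 2, params) == pytest.approx(
                expected_uniqueness(500, params), abs=1e-10
            )

    def test_kanon_montecarlo_oracle(self):
        params = PYParams(0.5, 10.0)
        n, k, reps = 2000, 5, 300
        vals = []
        for r in range(reps):
            c = sample_crp(n, params, seed=900 + r)
            vals.append(sum(s * m for s, m in c.sizes.items() if s < k) / n)
        mc, se = np.mean(vals), np.std(vals) / math.sqrt(reps)
        assert expected_kanon_violations(n, k, params) == pytest.approx(mc, abs=3 * se)

    def test_kanon_matches_generalized_hypergeometric_form(self):
        # the occupancy sum is an algebraic rewriting of the 3F2 expression
        # of the same expectation; check against a high-precision evaluation
        import mpmath as mp

        mp.mp.dps = 50
        for d, alpha in [(0.5, 10.0), (0.2, 1.0), (0.8, 0.5)]:
            params = PYParams(d, alpha)
            for n, k in [(2000, 5), (50, 3), (10, 2)]:
                nn, dd, aa = mp.mpf(n), mp.mpf(d), mp.mpf(alpha)
                pref = mp.binomial(nn - 1, nn - k + 1) * mp.gamma(k - dd) * mp.gamma(
                    nn - k + 1 + dd + aa
                )
                hyp = mp.hyper([1, nn, nn - k + 1 + dd + aa], [nn - k + 2, nn + 1 + aa], 1)
                ref = float(pref * hyp / (mp.beta(1 - dd, dd + aa) * mp.gamma(nn + 1 + aa)))
                assert expected_kanon_violations(n, k, params) == pytest.approx(ref, abs=1e-8)

    def test_extreme_entropy_regimes_stay_accurate(self):
        # huge-alpha / huge-n corners where naive log-gamma differencing loses
        # all precision; reference values frozen from a 150-digit evaluation
        cases = [
            (InfoParams(110.0, 0.3), 7.53e9, 1.0),
            (InfoParams.from_bits(40.0, 0.0), 7.53e9, 0.9939503121643076),
            (InfoParams.from_bits(40.0, 1.0), 7.53e9, 0.44764688647896567),
            (InfoParams(41.54, 0.68), 4e9, 0.743815017885974),
        ]
        for info, n, ref in cases:
            val = expected_correctness(n, py_from_info(info))
            assert val == pytest.approx(ref, rel=1e-9)

    def test_domain_errors(self):
        p = PYParams(0.5, 1.0)
        with pytest.raises(ValueError):
            expected_correctness(0, p)
        with pytest.raises(ValueError):
            expected_kanon_violations(10, 11, p)

    def test_stick_breaking_average_matches_prior_form(self):
        # averaging the finite-distribution correctness over prior draws
        # reproduces the closed-form prior expectation
        from reidscale import sample_stick_breaking

        params = PYParams(0.4, 3.0)
        n, reps = 200, 200
        vals = [
            correctness_from_frequencies(
                sample_stick_breaking(params, tail_mass_tol=1e-6, seed=r), n
            )
            for r in range(reps)
        ]
        se = np.std(vals) / math.sqrt(reps)
        assert np.mean(vals) == pytest.approx(expected_correctness(n, params), abs=3 * se)


class TestRegimes:
    def test_world_population_claims(self):
        # 40 bits of entropy: geometric tail keeps ~99% of the world
        # identifiable, the heaviest tail only ~45%
        n = 7.53e9
        k0 = expected_correctness(n, py_from_info(InfoParams.from_bits(40.0, 0.0)))
        k1 = expected_correctness(n, py_from_info(InfoParams.from_bits(40.0, 1.0)))
        assert round(100 * k0) == 99
        assert round(100 * k1) == 45

    def test_extended_regime_unique_record_trends(self):
        # number of unique records n*Xi: grows for heavy tails, flattens for
        # geometric tails, vanishes for finite near-uniform supports
        ns = np.logspace(2, 9.9, 25)
        h = 10.0 * math.log(2.0)
        growing = ns * expected_uniqueness(ns, py_from_info(InfoParams(h, 1.0)))
        flat = ns * expected_uniqueness(ns, py_from_info(InfoParams(h, 0.0)))
        dying = ns * expected_uniqueness(ns, py_from_info(InfoParams(h, -1.0)))
        assert np.all(np.diff(growing) > 0)
        # the geometric tail saturates at alpha unique records
        assert flat[-1] == pytest.approx(flat[-2], rel=1e-6)
        assert flat[-1] < 1e4  # bounded, unlike the heavy-tail case
        assert dying[-1] < dying[0] * 1e-3

    def test_criticality_window(self):
        # geometric tails show a sharp entropy threshold for identifiability;
        # heavy tails do not
        n = 7.53e9
        h_bits = np.linspace(1.0, 80.0, 400)

        def crossing_window(gamma):
            kappa = np.array(
                [
                    expected_correctness(n, py_from_info(InfoParams.from_bits(h, gamma)))
                    for h in h_bits
                ]
            )
            above = h_bits[kappa >= 0.95]
            below = h_bits[kappa <= 0.05]
            lo = below[-1] if below.size else h_bits[0]
            hi = above[0] if above.size else np.inf
            return hi - lo

        assert crossing_window(0.0) <= 10.0
        assert crossing_window(1.0) > 30.0


class TestHypothesisProperties:
    @given(
        st.floats(min_value=0.0, max_value=0.95),
        st.floats(min_value=0.1, max_value=100.0),
        st.integers(min_value=1, max_value=10**9),
    )
    @settings(deadline=None, max_examples=60)
    def test_probability_range(self, d, alpha, n):
        p = PYParams(d, alpha)
        for val in (expected_correctness(n, p), expected_uniqueness(n, p)):
            assert 0.0 <= val <= 1.0
        assert expected_kanon_violations(n, min(n, 5), p) <= 1.0
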