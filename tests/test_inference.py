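"""EPPF likelihood, MAP fitting, Pitman-Yor samplers and diagnostics."""

import math

import numpy as np
import pytest

from reidscale import (
    AnonymitySetCounts,
    FitConfig,
    PYParams,
    eppf_log_likelihood,
    expected_correctness,
    fit_map,
    kl_ranksize,
    posterior_predictive_bands,
    py_from_info,
    sample_crp,
    sample_stick_breaking,
)


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration oracle)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


class TestEppf:
    def test_hand_computed_pair_partitions(self):
        p = PYParams(0.5, 1.0)
        # two singletons: first new set w.p. 1, second w.p. (alpha+d)/(alpha+1)
        assert eppf_log_likelihood(AnonymitySetCounts({1: 2}), p) == pytest.approx(
            math.log(0.75), abs=1e-12
        )
        # one pair: second joins w.p. (1-d)/(alpha+1)
        assert eppf_log_likelihood(AnonymitySetCounts({2: 1}), p) == pytest.approx(
            math.log(0.25), abs=1e-12
        )

    @pytest.mark.parametrize("d,alpha", [(0.0, 1.0), (0.3, 0.5), (0.5, 1.0), (0.8, 5.0)])
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_normalization_over_partitions(self, d, alpha, n):
        # the EPPF is a probability distribution over set partitions of [n]
        p = PYParams(d, alpha)
        total = 0.0
        for partition in set_partitions(list(range(n))):
            counts = AnonymitySetCounts.from_sizes([len(b) for b in partition])
            total += math.exp(eppf_log_likelihood(counts, p))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_pole_approach_never_raises(self):
        # as d -> 1 the likelihood of any multi-record set sinks to -inf
        # smoothly (lgamma(1-d) diverges) instead of raising
        counts = AnonymitySetCounts({2: 1})
        vals = [
            eppf_log_likelihood(counts, PYParams(1 - eps, 0.5))
            for eps in (1e-4, 1e-8, 1e-12, 1e-15)
        ]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < -30

    def test_representation_invariance(self):
        # same multiset supplied in different representations -> same fit
        sizes = [4, 2, 2, 1, 1, 1]
        a = AnonymitySetCounts.from_sizes(sizes)
        b = AnonymitySetCounts({1: 3, 2: 2, 4: 1})
        p = PYParams(0.4, 2.0)
        assert eppf_log_likelihood(a, p) == eppf_log_likelihood(b, p)
        fa, _ = fit_map(a)
        fb, _ = fit_map(b)
        assert fa.h == fb.h and fa.gamma == fb.gamma


class TestFitMap:
    def test_recovers_simulation_parameters(self):
        counts = sample_crp(100_000, PYParams(0.5, 10.0), seed=42)
        info, diag = fit_map(counts)
        p = py_from_info(info)
        assert diag.converged
        assert p.d == pytest.approx(0.5, abs=0.05)
        assert p.alpha == pytest.approx(10.0, rel=0.5)

    def test_recovery_grid_median_error(self):
        # median |d_hat - d| across a 3x3 (d, alpha) grid at n=1e5
        errors = []
        for i, d in enumerate((0.2, 0.5, 0.8)):
            for j, alpha in enumerate((1.0, 10.0, 100.0)):
                counts = sample_crp(100_000, PYParams(d, alpha), seed=70 + 3 * i + j)
                info, _ = fit_map(counts)
                errors.append(abs(py_from_info(info).d - d))
        assert np.median(errors) < 0.05

    def test_all_singletons_flagged(self):
        info, diag = fit_map(AnonymitySetCounts({1: 500}))
        assert diag.boundary  # likelihood increases without bound
        assert info.h > 15.0  # pushed to the high-entropy boundary

    def test_single_set_flagged(self):
        info, diag = fit_map(AnonymitySetCounts({500: 1}))
        assert diag.boundary
        assert info.h < 0.1  # pinned at the low-entropy boundary

    def test_too_small_input(self):
        with pytest.raises(ValueError):
            fit_map(AnonymitySetCounts({1: 1}))

    def test_deterministic(self):
        counts = sample_crp(5000, PYParams(0.3, 5.0), seed=9)
        r1 = fit_map(counts, FitConfig())
        r2 = fit_map(counts, FitConfig())
        assert r1[0] == r2[0]


class TestSamplers:
    def test_crp_single_record(self):
        assert sample_crp(1, PYParams(0.5, 1.0), seed=0).sizes == {1: 1}

    def test_crp_tiny_concentration_is_one_table(self):
        counts = sample_crp(200, PYParams(0.0, 1e-9), seed=1)
        assert counts.sizes == {200: 1}

    def test_crp_mean_sets_match_expected_correctness(self):
        params = PYParams(0.5, 10.0)
        n, reps = 2000, 300
        vals = [sample_crp(n, params, seed=1000 + r).n_sets / n for r in range(reps)]
        se = np.std(vals) / math.sqrt(reps)
        assert np.mean(vals) == pytest.approx(expected_correctness(n, params), abs=3 * se)

    def test_crp_reproducible(self):
        p = PYParams(0.4, 3.0)
        assert sample_crp(500, p, seed=7).sizes == sample_crp(500, p, seed=7).sizes

    def test_stick_breaking_normalized_and_reproducible(self):
        p = PYParams(0.5, 1.0)
        f1 = sample_stick_breaking(p, seed=3)
        f2 = sample_stick_breaking(p, seed=3)
        assert f1.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(f1.p, f2.p)

    def test_stick_breaking_small_alpha_concentrates(self):
        f = sample_stick_breaking(PYParams(0.0, 0.01), seed=2)
        assert f.p.max() > 0.9

    def test_stick_breaking_truncation_flag(self):
        f = sample_stick_breaking(PYParams(0.9, 50.0), tail_mass_tol=1e-12, max_atoms=50, seed=1)
        assert f.truncated
        assert f.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stick_breaking_mean_entropy(self):
        # E[H(pi) | d, alpha] = psi0(alpha+1) - psi0(1-d) = 1 + 2 ln 2 here
        p = PYParams(0.5, 1.0)
        reps = 400
        ents = [
            sample_stick_breaking(p, tail_mass_tol=1e-9, seed=r).entropy() for r in range(reps)
        ]
        se = np.std(ents) / math.sqrt(reps)
        assert np.mean(ents) == pytest.approx(1.0 + 2.0 * math.log(2.0), abs=3 * se)

    def test_crp_and_stick_breaking_agree_on_set_counts(self):
        # the two constructions target the same partition law; compare the
        # distribution of the number of sets at n=200
        from scipy.stats import mannwhitneyu

        p = PYParams(0.5, 2.0)
        n, reps = 200, 400
        k_crp = [sample_crp(n, p, seed=r).n_sets for r in range(reps)]
        rng = np.random.default_rng(99)
        k_sb = []
        for r in range(reps):
            f = sample_stick_breaking(p, tail_mass_tol=1e-6, seed=rng)
            occ = rng.multinomial(n, f.p)
            k_sb.append(int(np.sum(occ > 0)))
        assert mannwhitneyu(k_crp, k_sb).pvalue > 0.01


class TestPredictiveChecks:
    def test_bands_are_sorted_and_degenerate_for_one_rep(self):
        p = PYParams(0.3, 5.0)
        env = posterior_predictive_bands(p, n=300, reps=1, seed=4)
        single = env["bands"][0]
        assert np.all(np.diff(single) <= 0)  # rank-size is non-increasing
        assert np.array_equal(env["bands"][0], env["bands"][-1])

    def test_envelope_calibration(self):
        # a 95% envelope from the true parameters should contain most
        # held-out simulated rank-size curves
        p = PYParams(0.4, 5.0)
        n = 300
        env = posterior_predictive_bands(p, n=n, reps=150, quantiles=(0.025, 0.975), seed=10)
        lo, hi = env["bands"]
        rng = np.random.default_rng(77)
        contained = 0
        held = 40
        for _ in range(held):
            f = sample_stick_breaking(p, tail_mass_tol=1e-6, seed=rng)
            occ = np.sort(rng.multinomial(n, f.p))[::-1]
            occ = occ[occ > 0]
            r = min(occ.size, lo.size)
            frac_in = np.mean((occ[:r] >= lo[:r]) & (occ[:r] <= hi[:r]))
            contained += frac_in > 0.9
        assert contained / held >= 0.9

    def test_kl_two_bin_hand_value(self):
        # direct check of the KL arithmetic on a two-bin case:
        # P=(.5,.5), Q=(.25,.75) -> 0.5 log2 2 + 0.5 log2 (2/3)
        from reidscale.params import LN2

        P = np.array([0.5, 0.5])
        Q = np.array([0.25, 0.75])
        expected = float(np.sum(P * np.log(P / Q)) / LN2)
        assert expected == pytest.approx(0.2075, abs=1e-4)

    def test_kl_self_consistency_and_nonnegativity(self):
        p = PYParams(0.5, 10.0)
        counts = sample_crp(20_000, p, seed=7)
        kl = kl_ranksize(counts, p, reps=30, seed=3)
        assert 0.0 <= kl < 0.5  # near zero when fitted params generated the data
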