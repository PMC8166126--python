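import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import betabinom as scipy_betabinom
from scipy.stats import binom

from aiselect import (
    FitOptions,
    ModelParams,
    Priors,
    betabinom_logpmf,
    expected_allele_fractions,
    fit_cohort,
    fit_map,
    fit_map_batch,
    log_likelihood,
    log_posterior,
)
from aiselect.model import _uniform_prior
from aiselect.simulate import SimulationConfig, simulate_cohort


class TestExpectedAlleleFractions:
    @pytest.mark.parametrize("pi,delta,phi,p_t,p_n", [
        (0.7, 0.0, 0.5, 0.7, 0.5),    # identity matrices leave pi unchanged
        (0.5, 0.02, 0.5, 0.5, 0.5),   # symmetry
        (0.5, 0.0, 0.6, 0.6, 0.6),    # pure mapping bias (2x2 product by hand)
        (0.62, 0.004, 0.52, 0.6377283850435532, 0.52),  # explicit matrix oracle
    ])
    def test_against_matrix_product_oracle(self, pi, delta, phi, p_t, p_n):
        out = expected_allele_fractions(ModelParams(pi, delta, phi, 50.0))
        assert out.p_tumor == pytest.approx(p_t, abs=1e-12)
        assert out.p_normal == pytest.approx(p_n, abs=1e-12)

    def test_matches_explicit_matrix_product(self, rng):
        for _ in range(20):
            pi, phi = rng.uniform(0.05, 0.95, 2)
            delta = rng.uniform(0.0, 0.1)
            v = np.array([1 - pi, pi])
            K = v @ np.array([[1 - delta, delta], [delta, 1 - delta]]) \
                  @ np.diag([2 * (1 - phi), 2 * phi])
            out = expected_allele_fractions(ModelParams(pi, delta, phi, 10.0))
            assert out.p_tumor == pytest.approx(K[1] / K.sum(), abs=1e-12)

    @given(pi1=st.floats(0.02, 0.98), pi2=st.floats(0.02, 0.98),
           delta=st.floats(0.0, 0.09), phi=st.floats(0.21, 0.79))
    @settings(max_examples=60, derandomize=True)
    def test_strictly_increasing_in_pi(self, pi1, pi2, delta, phi):
        if abs(pi1 - pi2) < 1e-9:
            return
        lo, hi = sorted([pi1, pi2])
        p_lo = expected_allele_fractions(ModelParams(lo, delta, phi, 10.0)).p_tumor
        p_hi = expected_allele_fractions(ModelParams(hi, delta, phi, 10.0)).p_tumor
        assert p_lo < p_hi

    def test_degenerate_fraction_signaled(self):
        with pytest.raises(ValueError, match="degenerate"):
            # subnormal pi underflows the tumor fraction to exactly 0
            expected_allele_fractions(ModelParams(5e-324, 0.0, 0.5, 10.0))


class TestBetaBinomLogpmf:
    def test_alpha_beta_one_gives_discrete_uniform(self):
        for k in range(11):
            assert betabinom_logpmf(k, 10, 0.5, 2.0) == pytest.approx(np.log(1 / 11))

    def test_normalization(self):
        total = sum(np.exp(betabinom_logpmf(k, 5, 0.3, 4.0)) for k in range(6))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_precision_limit_is_binomial(self):
        # the log-mass gap scales as n^2 / (2 theta), so theta = 1e6
        # brings every n=20 term within 1e-3 of the binomial
        for k in range(21):
            assert betabinom_logpmf(k, 20, 0.3, 1e6) == pytest.approx(
                binom.logpmf(k, 20, 0.3), abs=1e-3)

    def test_matches_scipy_parameterization(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            p = rng.uniform(0.05, 0.95)
            theta = rng.uniform(0.5, 500)
            assert betabinom_logpmf(k, n, p, theta) == pytest.approx(
                scipy_betabinom.logpmf(k, n, p * theta, (1 - p) * theta), rel=1e-10)

    @pytest.mark.parametrize("bad", [dict(k=5, n=3, p=0.5, theta=1),
                                     dict(k=1, n=3, p=0.0, theta=1),
                                     dict(k=1, n=3, p=0.5, theta=0)])
    def test_invalid_inputs_signaled(self, bad):
        with pytest.raises(ValueError):
            betabinom_logpmf(bad["k"], bad["n"], bad["p"], bad["theta"])


class TestLogLikelihood:
    def test_empty_sample_set_is_zero(self):
        assert log_likelihood(([], [], [], []), ModelParams(0.7, 0.0, 0.5, 50.0)) == 0.0

    def test_compositional_identity_single_sample(self):
        # tumor (yA=3, yB=7), normal (5, 5); A-side mean is 1 - p
        params = ModelParams(0.7, 0.0, 0.5, 50.0)
        got = log_likelihood(([3], [7], [5], [5]), params)
        want = betabinom_logpmf(3, 10, 0.3, 50.0) + betabinom_logpmf(5, 10, 0.5, 50.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_label_symmetry(self, rng):
        # swapping all A/B counts while mapping pi -> 1-pi, phi -> 1-phi
        # leaves the likelihood unchanged
        for _ in range(10):
            ta = rng.integers(0, 40, 6); tb = rng.integers(1, 40, 6)
            na = rng.integers(0, 40, 6); nb = rng.integers(1, 40, 6)
            pi, phi = rng.uniform(0.1, 0.9, 2)
            delta = rng.uniform(0.0, 0.08)
            theta = rng.uniform(2, 300)
            orig = log_likelihood((ta, tb, na, nb), ModelParams(pi, delta, phi, theta))
            swap = log_likelihood((tb, ta, nb, na),
                                  ModelParams(1 - pi, delta, 1 - phi, theta))
            assert swap == pytest.approx(orig, rel=1e-10)


class TestLogPosterior:
    COUNTS = ([12, 8, 20], [10, 14, 18], [11, 9, 19], [12, 11, 20])

    def test_flat_priors_shift_by_constant(self):
        flat = Priors(pi=_uniform_prior(0.01, 0.99),
                      delta=_uniform_prior(1e-6, 0.1),
                      phi=_uniform_prior(0.2, 0.8),
                      theta=_uniform_prior(1.0, 1e4))
        diffs = set()
        for pi in (0.3, 0.5, 0.8):
            p = ModelParams(pi, 0.01, 0.5, 60.0)
            diffs.add(round(log_posterior(p, self.COUNTS, flat)
                            - log_likelihood(self.COUNTS, p), 9))
        assert len(diffs) == 1

    def test_out_of_bounds_is_minus_infinity(self):
        p = ModelParams(0.999, 0.01, 0.5, 60.0)  # outside pi prior [0.01, 0.99]
        assert log_posterior(p, self.COUNTS) == -np.inf

    def test_hand_summed_prior_terms(self):
        priors = Priors()
        p = ModelParams(0.62, 0.004, 0.52, 80.0)
        by_hand = (float(priors.pi.log_density(np.asarray(0.62)))
                   + float(priors.delta.log_density(np.asarray(0.004)))
                   + float(priors.phi.log_density(np.asarray(0.52)))
                   + float(priors.theta.log_density(np.asarray(80.0))))
        assert log_posterior(p, self.COUNTS, priors) == pytest.approx(
            log_likelihood(self.COUNTS, p) + by_hand, rel=1e-12)


def _recovery_config(target_pi, n_samples, seed, n_snps=1, depth=80.0):
    """Config whose implied mean tumor B allocation equals target_pi:
    complete event rate, moderate imbalance, promotion probability solved
    from the target."""
    pf = 0.8
    w = (target_pi - (1 - pf)) / (2 * pf - 1)
    return SimulationConfig(
        n_snps=n_snps, n_samples=n_samples, snps_per_arm=1, coverage_mean=depth,
        het_prob=0.5, event_rate=1.0, promoted_fraction=pf, pi_true=w,
        delta_true=0.0, phi_true=0.5, theta_true=100.0, purity=1.0, seed=seed,
    )


class TestFitMap:
    def test_recovers_imbalanced_locus(self):
        cfg = _recovery_config(0.8, 200, seed=42)
        assert cfg.implied_pi()[0] == pytest.approx(0.8)
        sim = simulate_cohort(cfg)
        het = np.flatnonzero(sim.cohort.is_het[0])
        fit = fit_map((sim.cohort.tumor_a[0, het], sim.cohort.tumor_b[0, het],
                       sim.cohort.normal_a[0, het], sim.cohort.normal_b[0, het]))
        assert fit.converged
        assert abs(fit.params.pi - 0.8) < 0.05

    def test_map_beats_coarse_grid_oracle(self):
        cfg = _recovery_config(0.7, 80, seed=5)
        sim = simulate_cohort(cfg)
        het = np.flatnonzero(sim.cohort.is_het[0])
        counts = (sim.cohort.tumor_a[0, het], sim.cohort.tumor_b[0, het],
                  sim.cohort.normal_a[0, het], sim.cohort.normal_b[0, het])
        priors = Priors()
        fit = fit_map(counts, priors=priors)
        best_grid = -np.inf
        for pi in np.linspace(0.05, 0.95, 19):
            for phi in (0.35, 0.5, 0.65):
                for theta in (2, 10, 50, 200, 1000):
                    for delta in (1e-4, 0.01):
                        val = log_posterior(ModelParams(pi, delta, phi, theta),
                                            counts, priors)
                        best_grid = max(best_grid, val)
        assert fit.log_posterior >= best_grid - 1e-6

    def test_balanced_locus_recovers_half(self, balanced_sim):
        fits = fit_cohort(balanced_sim.cohort)
        assert fits["converged"].all()
        assert abs(fits["pi_hat"].mean() - 0.5) < 0.05

    def test_mapping_bias_absorbed_by_phi_not_pi(self):
        cfg = SimulationConfig(
            n_snps=10, n_samples=200, snps_per_arm=2, coverage_mean=80.0,
            event_rate=0.0, pi_true=0.5, delta_true=0.0, phi_true=0.6,
            theta_true=100.0, seed=17)
        fits = fit_cohort(simulate_cohort(cfg).cohort)
        assert abs(fits["pi_hat"].mean() - 0.5) < 0.05
        assert abs(fits["phi_hat"].mean() - 0.6) < 0.03

    def test_label_swap_maps_pi_to_one_minus_pi(self, eventful_sim):
        cohort = eventful_sim.cohort
        fits = fit_cohort(cohort)
        swapped = cohort.copy()
        swapped.tumor_a, swapped.tumor_b = cohort.tumor_b, cohort.tumor_a
        swapped.normal_a, swapped.normal_b = cohort.normal_b, cohort.normal_a
        fits_sw = fit_cohort(swapped)
        np.testing.assert_allclose(fits_sw["pi_hat"], 1 - fits["pi_hat"], atol=2e-3)
        np.testing.assert_allclose(fits_sw["phi_hat"], 1 - fits["phi_hat"], atol=2e-3)

    def test_warm_start_only_matches_multistart(self, eventful_sim):
        cohort = eventful_sim.cohort
        full = fit_cohort(cohort)
        warm = np.column_stack([
            np.full(cohort.n_snps, 0.5), full["delta_hat"],
            np.full(cohort.n_snps, 0.5), full["theta_hat"]])
        warm_only = fit_cohort(cohort, warm_start=warm, use_multistart=False)
        np.testing.assert_allclose(warm_only["pi_hat"], full["pi_hat"], atol=1e-3)

    def test_consistency_rmse_shrinks_with_cohort_size(self):
        errs = {}
        for n in (100, 200):
            cfg = _recovery_config(0.7, n, seed=400 + n, n_snps=50)
            sim = simulate_cohort(cfg)
            fits = fit_cohort(sim.cohort)
            errs[n] = float(np.sqrt(np.mean((fits["pi_hat"] - 0.7) ** 2)))
        assert errs[200] < errs[100]

    def test_fit_requires_informative_samples(self):
        with pytest.raises(ValueError, match="heterozygous"):
            fit_map(([], [], [], []))
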