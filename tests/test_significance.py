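import numpy as np
import pandas as pd
import pytest

from aiselect import (
    NullDistribution,
    build_null,
    call_selection,
    empirical_pvalue,
    permute_arm_labels,
    storey_qvalues,
)
from aiselect.model import fit_cohort
from aiselect.significance import draw_arm_swaps


class TestPermuteArmLabels:
    def test_forced_swap_mechanics(self, eventful_sim, rng):
        cohort = eventful_sim.cohort
        perm, swaps = permute_arm_labels(cohort, rng, return_swaps=True)
        arms, arm_idx = np.unique(cohort.loci["arm"].to_numpy(),
                                  return_inverse=True)
        s, a = np.argwhere(swaps)[0]
        snp = np.flatnonzero(arm_idx == a)[0]
        assert perm.tumor_a[snp, s] == cohort.tumor_b[snp, s]
        assert perm.tumor_b[snp, s] == cohort.tumor_a[snp, s]
        assert perm.normal_a[snp, s] == cohort.normal_b[snp, s]
        assert perm.normal_b[snp, s] == cohort.normal_a[snp, s]

    def test_all_or_none_within_sample_arm(self, eventful_sim, rng):
        cohort = eventful_sim.cohort
        perm = permute_arm_labels(cohort, rng)
        swapped = perm.tumor_a != cohort.tumor_a
        same_depth = cohort.tumor_a == cohort.tumor_b  # swap undetectable
        arm_idx = pd.factorize(cohort.loci["arm"])[0]
        for a in np.unique(arm_idx):
            rows = arm_idx == a
            for s in range(cohort.n_samples):
                detectable = rows & ~same_depth[:, s]
                flags = swapped[detectable, s]
                assert flags.all() or not flags.any()

    def test_totals_and_het_mask_unchanged(self, eventful_sim, rng):
        cohort = eventful_sim.cohort
        perm = permute_arm_labels(cohort, rng)
        np.testing.assert_array_equal(perm.tumor_a + perm.tumor_b,
                                      cohort.tumor_a + cohort.tumor_b)
        np.testing.assert_array_equal(perm.normal_a + perm.normal_b,
                                      cohort.normal_a + cohort.normal_b)
        np.testing.assert_array_equal(perm.is_het, cohort.is_het)

    def test_same_rng_state_identical(self, eventful_sim):
        cohort = eventful_sim.cohort
        a = permute_arm_labels(cohort, np.random.default_rng(5))
        b = permute_arm_labels(cohort, np.random.default_rng(5))
        np.testing.assert_array_equal(a.tumor_a, b.tumor_a)
        np.testing.assert_array_equal(a.normal_b, b.normal_b)

    def test_missing_arm_labels_rejected(self, eventful_sim, rng):
        cohort = eventful_sim.cohort.copy()
        cohort.loci = cohort.loci.drop(columns=["arm"])
        with pytest.raises(ValueError, match="arm"):
            permute_arm_labels(cohort, rng)


class TestBuildNull:
    def test_bookkeeping_pool_size(self, balanced_sim):
        cohort = balanced_sim.cohort
        null = build_null(cohort, n_perms=2, seed=1)
        assert null.size + null.n_dropped == 2 * cohort.n_snps
        assert null.n_perms == 2

    def test_pooled_values_in_range(self, balanced_sim):
        null = build_null(balanced_sim.cohort, n_perms=2, seed=1)
        assert null.pooled_stats.min() >= 0.0
        assert null.pooled_stats.max() <= 0.5

    def test_null_self_consistency_on_balanced_cohort(self, balanced_sim):
        # observed stats on a null cohort are exchangeable with permuted ones
        cohort = balanced_sim.cohort
        fits = fit_cohort(cohort)
        null = build_null(cohort, n_perms=4, seed=2, observed_fits=fits)
        obs = np.abs(0.5 - fits.loc[fits.converged, "pi_hat"].to_numpy())
        from scipy.stats import mannwhitneyu
        p = mannwhitneyu(obs, null.pooled_stats).pvalue
        assert p > 0.01

    def test_repermuting_is_idempotent_in_distribution(self, balanced_sim, rng):
        cohort = balanced_sim.cohort
        once = build_null(cohort, n_perms=3, seed=3)
        twice = build_null(permute_arm_labels(cohort, rng), n_perms=3, seed=3)
        from scipy.stats import ks_2samp
        assert ks_2samp(once.pooled_stats, twice.pooled_stats).pvalue > 0.01

    def test_tsv_roundtrip(self, balanced_sim, tmp_path):
        null = build_null(balanced_sim.cohort, n_perms=1, seed=4)
        path = tmp_path / "null.tsv"
        null.to_tsv(path)
        back = NullDistribution.from_tsv(path)
        assert back.n_perms == null.n_perms and back.seed == null.seed
        np.testing.assert_allclose(back.pooled_stats, null.pooled_stats,
                                   atol=1e-9)


class TestEmpiricalPvalue:
    def test_add_one_rule_extremes(self):
        null = NullDistribution(np.linspace(0.0, 0.4, 999), n_perms=1, seed=0)
        assert empirical_pvalue(0.45, null) == pytest.approx(1 / 1000)
        assert empirical_pvalue(0.0, null) == pytest.approx(1.0)

    def test_median_stat_gives_half(self):
        null = NullDistribution(np.linspace(0.0, 0.5, 1001), n_perms=1, seed=0)
        assert empirical_pvalue(0.25, null) == pytest.approx(0.5, abs=0.01)

    def test_empty_null_rejected(self):
        null = NullDistribution(np.empty(0), n_perms=0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            empirical_pvalue(0.1, null)


class TestStoreyQvalues:
    def test_uniform_pvalues_pi0_near_one(self):
        rng = np.random.default_rng(123)
        p = rng.uniform(1e-9, 1.0, 2000)
        q = storey_qvalues(p)
        # the q-value at the largest p equals pi0 * p_max, so back out pi0
        pi0 = q[np.argmax(p)] / p.max()
        assert 0.85 <= pi0 <= 1.0

    def test_bh_fallback_largest_p_maps_to_itself(self):
        p = np.array([0.01, 0.2, 0.9])  # fewer than 10: pi0 fixed at 1
        q = storey_qvalues(p)
        assert q[2] == pytest.approx(0.9)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = np.clip(rng.beta(0.6, 3.0, 500), 1e-9, 1.0)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])


class TestCallSelection:
    @staticmethod
    def _fits(pis):
        return pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(len(pis))],
            "pi_hat": pis,
            "delta_hat": 0.002, "phi_hat": 0.5, "theta_hat": 100.0,
            "n_het": 50, "log_posterior": -100.0, "converged": True,
        })

    def test_strong_call_significant_at_all_levels(self):
        null = NullDistribution(np.linspace(0.0, 0.1, 4000), n_perms=1, seed=0)
        calls = call_selection(self._fits([0.72]), null)
        row = calls.iloc[0]
        assert row["direction"] == "selected_for"
        assert row["p_emp"] < 0.001
        assert row["sig_0.05"] and row["sig_0.01"] and row["sig_0.001"]

    def test_significant_sets_are_nested(self, rng):
        null = NullDistribution(rng.uniform(0, 0.2, 5000), n_perms=1, seed=0)
        calls = call_selection(self._fits(rng.uniform(0.2, 0.8, 200)), null)
        assert (calls["sig_0.001"] <= calls["sig_0.01"]).all()
        assert (calls["sig_0.01"] <= calls["sig_0.05"]).all()

    def test_exact_half_has_no_direction(self):
        null = NullDistribution(np.linspace(0.0, 0.5, 100), n_perms=1, seed=0)
        calls = call_selection(self._fits([0.5, 0.49]), null)
        assert calls.iloc[0]["direction"] == "none"
        assert calls.iloc[1]["direction"] == "selected_against"


def test_draw_arm_swaps_is_fair(rng):
    swaps = draw_arm_swaps(2000, 1, rng)
    assert abs(swaps.mean() - 0.5) < 0.03
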