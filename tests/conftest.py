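import numpy as np
import pytest

from aiselect import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def balanced_sim():
    """Small fully-null cohort: no AI events, no technical bias."""
    cfg = SimulationConfig(
        n_snps=30, n_samples=60, snps_per_arm=5, coverage_mean=60.0,
        het_prob=0.5, event_rate=0.0, pi_true=0.5, delta_true=0.0,
        phi_true=0.5, theta_true=100.0, purity=1.0, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def eventful_sim():
    """Cohort with neutral AI events (promotion is a fair coin)."""
    cfg = SimulationConfig(
        n_snps=24, n_samples=40, snps_per_arm=4, coverage_mean=60.0,
        het_prob=0.5, event_rate=0.5, promoted_fraction=0.7, pi_true=0.5,
        delta_true=0.002, phi_true=0.5, theta_true=100.0, purity=0.9, seed=21,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
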