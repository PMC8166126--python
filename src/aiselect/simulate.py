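"""Synthetic paired tumor/normal allelic-count cohorts with ground truth.

The generator is the forward model of the analysis: heterozygous genotypes
with random phase, arm-level allelic-imbalance (AI) events that promote one
parental homolog consistently across an arm, beta-binomial overdispersed
counts, base-calling error, reference-mapping bias, and normal-cell
contamination (a linear mixture of the tumor allele fraction toward the
balanced 0.5 before counts are drawn).

Selection enters through the per-SNP parameter ``pi_true``: when an AI event
fires on a (sample, arm), the promoted homolog is the one carrying the B
allele of the arm's selection driver with probability pi (the driver is one
non-neutral heterozygous SNP on the arm, chosen uniformly; arms with only
neutral SNPs promote either homolog with probability 1/2). Placing at most
one non-neutral SNP per arm makes the marginal promotion probability equal
pi_true exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortCounts, set_het_mask

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "AnnotationTables",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_annotations",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    coverage_mean is the mean of the per-site total depth (negative binomial
    with dispersion ``depth_dispersion``); ``promoted_fraction`` is the
    expected tumor B-homolog fraction at AI sites when the B-carrying
    homolog is promoted; ``purity`` mixes the tumor allele fraction toward
    0.5 by 1 - purity before counts are drawn.
    """

    n_snps: int
    n_samples: int
    snps_per_arm: int = 20
    coverage_mean: float = 60.0
    het_prob: float = 0.5
    event_rate: float = 0.3
    promoted_fraction: float = 0.7
    pi_true: Union[float, tuple, np.ndarray] = 0.5
    delta_true: float = 0.002
    phi_true: float = 0.5
    theta_true: float = 100.0
    purity: float = 1.0
    depth_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_snps", self.n_snps >= 1),
            ("n_samples", self.n_samples >= 1),
            ("snps_per_arm", self.snps_per_arm >= 1),
            ("coverage_mean", self.coverage_mean >= 1),
            ("het_prob", 0.0 <= self.het_prob <= 1.0),
            ("event_rate", 0.0 <= self.event_rate <= 1.0),
            ("promoted_fraction", 0.0 <= self.promoted_fraction <= 1.0),
            ("delta_true", 0.0 <= self.delta_true <= 0.1),
            ("phi_true", 0.0 < self.phi_true < 1.0),
            ("theta_true", self.theta_true > 0.0),
            ("purity", 0.0 <= self.purity <= 1.0),
            ("depth_dispersion", self.depth_dispersion > 0.0),
            ("seed", int(self.seed) == self.seed),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SimulationConfig field: {name}")
        pi = self.pi_vector()
        if np.any(pi < 0.0) or np.any(pi > 1.0):
            raise ValueError("invalid SimulationConfig field: pi_true")
        if pi.size not in (1, self.n_snps):
            raise ValueError("invalid SimulationConfig field: pi_true (length)")

    def pi_vector(self) -> np.ndarray:
        pi = np.atleast_1d(np.asarray(self.pi_true, dtype=float))
        if pi.size == 1:
            pi = np.full(self.n_snps, float(pi[0]))
        return pi

    @property
    def n_arms(self) -> int:
        return math.ceil(self.n_snps / self.snps_per_arm)

    def implied_pi(self) -> np.ndarray:
        """Per-SNP expected tumor B-allele allocation at heterozygous sites.

        This is the quantity the selection model's pi estimates: the model
        averages the allelic allocation over samples, so discrete AI events
        of magnitude ``promoted_fraction`` firing at ``event_rate`` with
        B-homolog promotion probability ``pi_true`` are seen through their
        marginal mean, attenuated toward 0.5 by incomplete imbalance,
        sub-unit event rates, and normal contamination.
        """
        pi = self.pi_vector()
        pf, r = self.promoted_fraction, self.event_rate
        at_event = pf * pi + (1.0 - pf) * (1.0 - pi)
        mean_f = (1.0 - r) * 0.5 + r * at_event
        return self.purity * mean_f + (1.0 - self.purity) * 0.5

    def to_yaml(self, path) -> None:
        data = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump({"simulation": data}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        section = data.get("simulation", data)
        if "seed" not in section:
            raise ValueError("simulation config must specify a seed")
        if isinstance(section.get("pi_true"), list):
            section["pi_true"] = np.asarray(section["pi_true"], dtype=float)
        return cls(**section)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulated cohort.

    ``promoted_homolog`` is -1 where no AI event fired; within one
    (sample, arm) every SNP shares the promoted-homolog label by
    construction. ``phase`` gives, per (SNP, sample), the homolog (0/1)
    carrying the B allele (meaningful at truly heterozygous entries).
    """

    pi_true: np.ndarray                 # (n_snps,)
    event: np.ndarray                   # (n_samples, n_arms) bool
    promoted_homolog: np.ndarray        # (n_samples, n_arms) int, -1 = none
    phase: np.ndarray                   # (n_snps, n_samples) int {0,1}
    is_het_true: np.ndarray             # (n_snps, n_samples) bool
    arm_index: np.ndarray               # (n_snps,) int
    arms: tuple[str, ...]

    def b_promoted(self) -> np.ndarray:
        """(n_snps, n_samples) bool: AI event on the SNP's arm promoted the
        homolog carrying this sample's B allele."""
        ev = self.event[:, self.arm_index].T
        prom = self.promoted_homolog[:, self.arm_index].T
        return ev & (prom == self.phase)

    def to_frame(self) -> pd.DataFrame:
        snp = np.repeat(np.arange(self.phase.shape[0]), self.phase.shape[1])
        samp = np.tile(np.arange(self.phase.shape[1]), self.phase.shape[0])
        return pd.DataFrame({
            "snp_index": snp,
            "sample_index": samp,
            "arm": np.asarray(self.arms)[self.arm_index][snp],
            "pi_true": self.pi_true[snp],
            "is_het_true": self.is_het_true.ravel(),
            "phase_b_homolog": self.phase.ravel(),
            "event": self.event[:, self.arm_index].T.ravel()[
                np.arange(snp.size)],
            "b_promoted": self.b_promoted().ravel(),
        })


@dataclass(frozen=True)
class AnnotationTables:
    """Per-SNP annotation table and per-gene dependency table."""

    snps: pd.DataFrame   # snp_id, gene, maf, cadd, control_af
    genes: pd.DataFrame  # gene, dependency_score


@dataclass(frozen=True)
class SyntheticCohort:
    cohort: CohortCounts
    truth: TruthTable
    annotations: AnnotationTables
    config: SimulationConfig


def _negative_binomial_depth(rng, mean, dispersion, size):
    """Total depth with var = mean + dispersion * mean^2, floored at 1."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return np.maximum(rng.negative_binomial(r, p, size=size), 1)


def _betabinom_counts(rng, n, p, theta):
    """Draw B counts ~ beta-binomial(n, mean p, precision theta); the
    boundary means 0 and 1 degenerate to all-A / all-B draws."""
    q = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    q[interior] = rng.beta(p[interior] * theta, (1.0 - p[interior]) * theta)
    q[~interior] = p[~interior]
    return rng.binomial(n, q)


def _choose_promoted(rng, config, pi, het, phase, arm_index, event):
    """Promoted-homolog label per (sample, arm): follow the arm's selection
    driver with probability pi(driver), else a fair coin."""
    n_samples, n_arms = event.shape
    promoted = np.full((n_samples, n_arms), -1, dtype=np.int64)
    coin = rng.integers(0, 2, size=(n_samples, n_arms))
    u = rng.random((n_samples, n_arms))
    nonneutral = np.abs(pi - 0.5) > 1e-12
    for a in range(n_arms):
        snps = np.flatnonzero(arm_index == a)
        drivers = snps[nonneutral[snps]]
        ev = event[:, a]
        if drivers.size == 0:
            promoted[ev, a] = coin[ev, a]
            continue
        for s in np.flatnonzero(ev):
            het_drivers = drivers[het[drivers, s]]
            if het_drivers.size == 0:
                promoted[s, a] = coin[s, a]
                continue
            d = het_drivers[0] if het_drivers.size == 1 else rng.choice(het_drivers)
            follow_b = u[s, a] < pi[d]
            promoted[s, a] = phase[d, s] if follow_b else 1 - phase[d, s]
    return promoted


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one synthetic cohort (counts + truth + annotations).

    Regenerating with the same config and seed is bit-identical. The
    analysis-facing het mask is set from the simulated normal counts with
    the same caller the real pipeline uses, so low-coverage true hets can be
    missed, exactly as in real data.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, config.n_samples
    n_arms = config.n_arms
    pi = config.pi_vector()

    arm_index = np.repeat(np.arange(n_arms), config.snps_per_arm)[:n]
    arm_names = tuple(f"{a // 2 + 1}{'pq'[a % 2]}" for a in range(n_arms))
    maf = 0.5 * rng.beta(1.2, 3.0, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    loci = pd.DataFrame({
        "snp_id": [f"rs{1000000 + i}" for i in range(n)],
        "chrom": [str(a // 2 + 1) for a in arm_index],
        "pos": (np.arange(n, dtype=np.int64) % config.snps_per_arm + 1) * 1000
               + (arm_index % 2) * 50_000_000,
        "arm": [arm_names[a] for a in arm_index],
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "gene": [f"GENE{i // 4 + 1}" for i in range(n)],
        "maf": maf,
    })

    het = rng.random((n, m)) < config.het_prob
    phase = rng.integers(0, 2, size=(n, m))
    event = rng.random((m, n_arms)) < config.event_rate
    promoted = _choose_promoted(rng, config, pi, het, phase, arm_index, event)

    # homozygous genotypes: P(hom-alt | not het) from the population MAF
    p_homalt = maf**2 / ((1.0 - maf) ** 2 + maf**2)
    hom_alt = (rng.random((n, m)) < p_homalt[:, None]) & ~het

    # tumor B-homolog fraction before contamination/bias
    ev_snp = event[:, arm_index].T
    b_prom = ev_snp & (promoted[:, arm_index].T == phase)
    f_tumor = np.where(het, 0.5, np.where(hom_alt, 1.0, 0.0))
    f_tumor = np.where(het & ev_snp,
                       np.where(b_prom, config.promoted_fraction,
                                1.0 - config.promoted_fraction),
                       f_tumor)
    f_tumor = config.purity * f_tumor + (1.0 - config.purity) * np.where(
        het, 0.5, f_tumor)
    f_normal = np.where(het, 0.5, np.where(hom_alt, 1.0, 0.0))

    p_obs_t = _tumor_mean_fraction(f_tumor, config.delta_true, config.phi_true)
    p_obs_n = _tumor_mean_fraction(f_normal, config.delta_true, config.phi_true)

    depth_t = _negative_binomial_depth(rng, config.coverage_mean,
                                       config.depth_dispersion, (n, m))
    depth_n = _negative_binomial_depth(rng, config.coverage_mean,
                                       config.depth_dispersion, (n, m))
    tumor_b = _betabinom_counts(rng, depth_t, p_obs_t, config.theta_true)
    normal_b = _betabinom_counts(rng, depth_n, p_obs_n, config.theta_true)

    cohort = CohortCounts(
        loci=loci, samples=[f"S{j:04d}" for j in range(m)],
        tumor_a=depth_t - tumor_b, tumor_b=tumor_b,
        normal_a=depth_n - normal_b, normal_b=normal_b,
    )
    set_het_mask(cohort)

    truth = TruthTable(pi_true=pi, event=event, promoted_homolog=promoted,
                       phase=phase, is_het_true=het, arm_index=arm_index,
                       arms=arm_names)
    ann = simulate_annotations(
        _Partial(cohort=cohort, truth=truth, config=config),
        assoc_strength=0.0, seed=int(rng.integers(0, 2**31 - 1)))
    return SyntheticCohort(cohort=cohort, truth=truth, annotations=ann,
                           config=config)


@dataclass(frozen=True)
class _Partial:
    """Minimal view of a cohort used while assembling a SyntheticCohort."""
    cohort: CohortCounts
    truth: TruthTable
    config: SimulationConfig


def _tumor_mean_fraction(f, delta, phi):
    """Observed B-read fraction after base-calling error and mapping bias;
    the same mean map the inference model inverts, applied to any latent
    allele fraction f (not just (1-pi, pi))."""
    b = delta + f * (1.0 - 2.0 * delta)
    return phi * b / (phi * b + (1.0 - phi) * (1.0 - b))


def simulate_annotations(cohort, assoc_strength: float = 0.0,
                         seed: int = 0) -> AnnotationTables:
    """Per-SNP CADD-like scores and control allele frequencies, plus
    per-gene dependency scores, with optional planted association.

    With ``assoc_strength`` > 0, SNPs whose true pi is far from 0.5 receive
    stochastically higher deleteriousness scores, control frequencies
    shifted against the direction of selection (selected-for alleles look
    more frequent in cases), and their genes get lower (more essential)
    dependency scores. ``assoc_strength = 0`` plants nothing.
    """
    rng = np.random.default_rng(seed)
    loci = cohort.cohort.loci
    pi = cohort.truth.pi_true
    n = len(loci)
    sel = np.abs(pi - 0.5)

    cadd = rng.gamma(2.0, 4.0, size=n)
    cadd = cadd + assoc_strength * sel * 2.0 * rng.exponential(1.0, size=n)

    # control AF anchored on the realized germline allele frequency so the
    # case/control comparison is null unless an association is planted
    gt = cohort.cohort.normal_b / np.maximum(
        cohort.cohort.normal_a + cohort.cohort.normal_b, 1)
    called = (cohort.cohort.normal_a + cohort.cohort.normal_b) > 20
    n_b = np.where(called, (gt > 0.8) * 2 + ((gt >= 0.2) & (gt <= 0.8)) * 1, 0)
    case_af = n_b.sum(axis=1) / np.maximum(2 * called.sum(axis=1), 1)
    shift = assoc_strength * (pi - 0.5) * 0.2
    noise = rng.normal(0.0, 0.01, size=n)
    control_af = np.clip(case_af - shift + noise, 1e-3, 1.0 - 1e-3)

    snps = pd.DataFrame({
        "snp_id": loci["snp_id"].to_numpy(),
        "gene": loci["gene"].to_numpy() if "gene" in loci else
                [f"GENE{i // 4 + 1}" for i in range(n)],
        "maf": loci["maf"].to_numpy() if "maf" in loci else np.full(n, np.nan),
        "cadd": cadd,
        "control_af": control_af,
    })

    genes = snps[["gene"]].drop_duplicates().reset_index(drop=True)
    base = rng.normal(0.0, 0.3, size=len(genes))
    sel_for = pd.Series(np.where(pi > 0.5, sel, 0.0)).groupby(
        snps["gene"].to_numpy()).max()
    genes["dependency_score"] = base - assoc_strength * 0.5 * sel_for.reindex(
        genes["gene"]).fillna(0.0).to_numpy()
    return AnnotationTables(snps=snps, genes=genes)
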