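"""Permutation null, pooled empirical p-values, Storey q-values, calls.

The null hypothesis is "no preference for either parental allele": it is
realized by swapping, independently for each (sample, chromosome-arm) pair
with probability 1/2, the A and B labels of every SNP on that arm in both
the tumor and the matched normal. Because all alleles on the arm swap (or
none do), phase within allelic-imbalance events is preserved — the only
thing randomized is which parental homolog acquired the event. The test
statistic abs(0.5 - pi_hat) is pooled across all permutations and SNPs into
one null distribution, from which empirical p-values and Storey q-values
are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .cohort import CohortCounts
from .model import FitOptions, Priors, fit_cohort, fit_map_batch

__all__ = [
    "NullDistribution",
    "permute_arm_labels",
    "draw_arm_swaps",
    "build_null",
    "empirical_pvalue",
    "storey_qvalues",
    "call_selection",
]


@dataclass(frozen=True)
class NullDistribution:
    """Pooled permutation draws of abs(0.5 - pi_hat)."""

    pooled_stats: np.ndarray  # sorted ascending
    n_perms: int
    seed: int
    n_dropped: int = 0  # non-converged permutation fits excluded from the pool

    def __post_init__(self) -> None:
        stats = np.sort(np.asarray(self.pooled_stats, dtype=float))
        if stats.size and (stats[0] < -1e-12 or stats[-1] > 0.5 + 1e-12):
            raise ValueError("pooled statistics must lie in [0, 0.5]")
        object.__setattr__(self, "pooled_stats", stats)

    @property
    def size(self) -> int:
        return int(self.pooled_stats.size)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_perms={self.n_perms} seed={self.seed} "
                     f"n_dropped={self.n_dropped}\n")
            fh.write("abs_half_minus_pi\n")
            np.savetxt(fh, self.pooled_stats, fmt="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "NullDistribution":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        stats = np.loadtxt(path, skiprows=2, ndmin=1)
        return cls(pooled_stats=stats, n_perms=int(meta["n_perms"]),
                   seed=int(meta["seed"]), n_dropped=int(meta["n_dropped"]))


def draw_arm_swaps(n_samples: int, n_arms: int, rng) -> np.ndarray:
    """Bernoulli(1/2) swap decisions, one per (sample, arm)."""
    return rng.random((n_samples, n_arms)) < 0.5


def permute_arm_labels(cohort: CohortCounts, rng,
                       return_swaps: bool = False):
    """One draw of the arm-swap permutation.

    For each (sample, arm) independently, with probability 1/2 the A and B
    counts of every SNP on that arm are exchanged in both tumor and normal
    (all-or-none per sample-arm, so phase is preserved); totals and the het
    mask are unchanged (the het BAF window is symmetric).
    """
    if "arm" not in cohort.loci.columns or cohort.loci["arm"].isna().any():
        raise ValueError("cohort loci must carry arm labels to permute")
    arms, arm_idx = np.unique(cohort.loci["arm"].to_numpy(), return_inverse=True)
    swaps = draw_arm_swaps(cohort.n_samples, len(arms), rng)
    swap_grid = swaps[:, arm_idx].T  # (n_snps, n_samples)

    out = cohort.copy()
    out.tumor_a = np.where(swap_grid, cohort.tumor_b, cohort.tumor_a)
    out.tumor_b = np.where(swap_grid, cohort.tumor_a, cohort.tumor_b)
    out.normal_a = np.where(swap_grid, cohort.normal_b, cohort.normal_a)
    out.normal_b = np.where(swap_grid, cohort.normal_a, cohort.normal_b)
    if return_swaps:
        return out, swaps
    return out


def build_null(cohort: CohortCounts, n_perms: int, seed: int,
               priors: Priors | None = None,
               options: FitOptions | None = None,
               observed_fits: pd.DataFrame | None = None,
               chunk_perms: int = 8) -> NullDistribution:
    """Pooled permutation null of abs(0.5 - pi_hat).

    Every permutation relabels arms and refits all four model parameters at
    every SNP; the statistics are pooled across permutations and SNPs.
    Refits warm-start from the observed fit's nuisance estimates (delta,
    theta) with pi and phi reset to their null centers — a single smart
    start, verified against the full multi-start. Permutations are refit in
    chunks as one stacked batch for speed; results are identical to
    one-at-a-time refits because the posterior is separable across SNPs.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    priors = priors or Priors()
    options = options or FitOptions()
    rng = np.random.default_rng(seed)

    if observed_fits is None:
        observed_fits = fit_cohort(cohort, priors=priors, options=options)
    warm = np.column_stack([
        np.full(cohort.n_snps, 0.5),
        observed_fits["delta_hat"].to_numpy(),
        np.full(cohort.n_snps, 0.5),
        observed_fits["theta_hat"].to_numpy(),
    ])

    pooled: list[np.ndarray] = []
    n_dropped = 0
    done = 0
    while done < n_perms:
        k = min(chunk_perms, n_perms - done)
        perms = [permute_arm_labels(cohort, rng) for _ in range(k)]
        res = fit_map_batch(
            np.vstack([p.tumor_a for p in perms]),
            np.vstack([p.tumor_b for p in perms]),
            np.vstack([p.normal_a for p in perms]),
            np.vstack([p.normal_b for p in perms]),
            np.vstack([p.is_het for p in perms]),
            priors=priors, options=options,
            warm_start=np.tile(warm, (k, 1)), use_multistart=False,
        )
        ok = res["converged"] & (res["n_het"] >= 1)
        n_dropped += int((~ok).sum())
        pooled.append(np.abs(0.5 - res["params"][ok, 0]))
        done += k

    stats = np.concatenate(pooled) if pooled else np.empty(0)
    if stats.size == 0:
        raise RuntimeError("all permutation fits failed; null is empty")
    return NullDistribution(pooled_stats=stats, n_perms=n_perms, seed=seed,
                            n_dropped=n_dropped)


def empirical_pvalue(stat, null: NullDistribution):
    """Pooled empirical p-value with the add-one rule:
    p = (1 + #{null >= stat}) / (1 + pool size), guaranteeing p > 0."""
    if null.size == 0:
        raise ValueError("null distribution is empty")
    stat = np.asarray(stat, dtype=float)
    n_ge = null.size - np.searchsorted(null.pooled_stats, stat, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    return p if p.ndim else float(p)


def storey_qvalues(pvals, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey FDR q-values from empirical p-values.

    pi0 (the null proportion) is estimated on a lambda grid from the
    p-value histogram, smoothed with a cubic spline and read off at the
    largest lambda; q-values are the running minimum of pi0 * m * p / rank
    from the largest p down, so they are monotone in p. Fewer than 10
    p-values falls back to pi0 = 1 (the Benjamini-Hochberg estimator).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)

    if p.size < 10:
        pi0 = 1.0
    else:
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        try:
            spline = UnivariateSpline(lambdas, pi0_lam, k=3)
            pi0 = float(spline(lambdas[-1]))
        except Exception:
            pi0 = float(pi0_lam[-1])
        pi0 = min(max(pi0, 1.0 / p.size), 1.0)

    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_selection(fits: pd.DataFrame, null: NullDistribution,
                   alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
                   q_cut: float = 0.1) -> pd.DataFrame:
    """Per-SNP selection calls from converged fits and the pooled null.

    direction is "selected_for" when pi_hat > 0.5 (positive selection of
    the B allele), "selected_against" when pi_hat < 0.5, and "none" at
    exactly 0.5. ``sig_<alpha>`` columns mark empirical p below each nominal
    level (nested by construction); ``pass_q`` marks q below ``q_cut``.
    """
    fits = fits[fits["converged"]].reset_index(drop=True)
    pi_hat = fits["pi_hat"].to_numpy()
    stat = np.abs(0.5 - pi_hat)
    p_emp = np.asarray(empirical_pvalue(stat, null))
    q = storey_qvalues(p_emp)
    direction = np.where(pi_hat > 0.5, "selected_for",
                         np.where(pi_hat < 0.5, "selected_against", "none"))
    out = pd.DataFrame({
        "snp_id": fits["snp_id"],
        "pi_hat": pi_hat,
        "stat": stat,
        "p_emp": p_emp,
        "q": q,
        "direction": direction,
    })
    for a in alphas:
        out[f"sig_{a}"] = p_emp < a
    out["pass_q"] = q < q_cut
    return out
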