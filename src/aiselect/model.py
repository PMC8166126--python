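"""Per-SNP Bayesian beta-binomial model of tumor allelic preference.

At a heterozygous SNP, the tumor B-allele read count (conditional on the
site's total depth) is beta-binomial with mean ``p`` and precision ``theta``.
The mean encodes three SNP-level quantities:

* ``pi`` — the cohort-level preference for promotion of the B allele over
  the A allele (0.5 = no somatic selection);
* ``delta`` — base-calling error, which mixes reads between the two alleles
  and shrinks the signal toward 0.5;
* ``phi`` — reference-mapping bias (A = reference, B = alternate), which
  distorts both tumor and normal allele fractions.

The matched normal sample carries no selection signal (both alleles equally
represented), so its expected B fraction depends only on ``delta`` and
``phi``; jointly modelling tumor and normal counts is what makes ``pi``
identifiable separately from the technical biases.

The MAP estimate of (pi, delta, phi, theta) is obtained by bounded
quasi-Newton (L-BFGS-B) maximization of the log posterior in transformed
coordinates (scaled logit for the bounded parameters, log-scaled logit for
theta), with analytic gradients and a deterministic multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.special import betaln, gammaln, psi
from scipy.stats import beta as beta_dist

__all__ = [
    "ModelParams",
    "ExpectedAllocation",
    "PriorSpec",
    "Priors",
    "FitOptions",
    "ModelFit",
    "expected_allele_fractions",
    "betabinom_logpmf",
    "log_likelihood",
    "log_posterior",
    "fit_map",
    "fit_map_batch",
    "fit_cohort",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ModelParams:
    """The quadruple (pi, delta, phi, theta) of the per-SNP model."""

    pi: float
    delta: float
    phi: float
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValueError(f"pi must be in (0, 1), got {self.pi}")
        if not (0.0 <= self.delta <= 0.1):
            raise ValueError(f"delta must be in [0, 0.1], got {self.delta}")
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if not (self.theta > 0.0 and np.isfinite(self.theta)):
            raise ValueError(f"theta must be positive and finite, got {self.theta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pi, self.delta, self.phi, self.theta], dtype=float)


@dataclass(frozen=True)
class ExpectedAllocation:
    """Expected tumor and normal B-allele fractions implied by ModelParams."""

    p_tumor: float
    p_normal: float


@dataclass(frozen=True)
class PriorSpec:
    """Bounded prior for one parameter: interval plus log-density on it."""

    lower: float
    upper: float
    log_density: Callable[[np.ndarray], np.ndarray]
    dlog_density: Callable[[np.ndarray], np.ndarray]
    log_scale: bool = False  # optimize this coordinate on a log grid

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("prior bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError("prior lower bound must be below upper bound")


def _uniform_prior(lo: float, hi: float, log_scale: bool = False) -> PriorSpec:
    c = -np.log(hi - lo)
    return PriorSpec(lo, hi, lambda x: np.full_like(np.asarray(x, float), c),
                     lambda x: np.zeros_like(np.asarray(x, float)), log_scale)


def _trunc_beta_prior(a: float, b: float, lo: float, hi: float) -> PriorSpec:
    norm = np.log(beta_dist.cdf(hi, a, b) - beta_dist.cdf(lo, a, b))

    def logpdf(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b) - norm

    def dlogpdf(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return (a - 1.0) / x - (b - 1.0) / (1.0 - x)

    return PriorSpec(lo, hi, logpdf, dlogpdf)


def _log_uniform_prior(lo: float, hi: float) -> PriorSpec:
    c = -np.log(np.log(hi / lo))

    def logpdf(x: np.ndarray) -> np.ndarray:
        return c - np.log(np.asarray(x, float))

    def dlogpdf(x: np.ndarray) -> np.ndarray:
        return -1.0 / np.asarray(x, float)

    return PriorSpec(lo, hi, logpdf, dlogpdf, log_scale=True)


@dataclass(frozen=True)
class Priors:
    """Independent priors over (pi, delta, phi, theta).

    Defaults: pi uniform on [0.01, 0.99]; delta Beta(1, 50) truncated to
    [1e-6, 0.1]; phi Beta(20, 20) truncated to [0.2, 0.8] (centered on no
    mapping bias); theta log-uniform on [1, 1e4]. These are documented
    stand-ins — every piece is configurable.
    """

    pi: PriorSpec = field(default_factory=lambda: _uniform_prior(0.01, 0.99))
    delta: PriorSpec = field(default_factory=lambda: _trunc_beta_prior(1.0, 50.0, 1e-6, 0.1))
    phi: PriorSpec = field(default_factory=lambda: _trunc_beta_prior(20.0, 20.0, 0.2, 0.8))
    theta: PriorSpec = field(default_factory=lambda: _log_uniform_prior(1.0, 1e4))

    def specs(self) -> tuple[PriorSpec, PriorSpec, PriorSpec, PriorSpec]:
        return (self.pi, self.delta, self.phi, self.theta)

    def contains(self, params: ModelParams) -> bool:
        vals = params.as_array()
        return all(s.lower <= v <= s.upper for s, v in zip(self.specs(), vals))

    def log_density(self, params: ModelParams) -> float:
        if not self.contains(params):
            return -np.inf
        vals = params.as_array()
        return float(sum(float(s.log_density(np.asarray(v))) for s, v in zip(self.specs(), vals)))


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for the MAP fit.

    starts: deterministic multi-start points (pi, delta, phi, theta); ties
    between starts are broken toward pi closest to 0.5 (conservative).
    """

    starts: tuple[tuple[float, float, float, float], ...] = (
        (0.3, 0.005, 0.5, 100.0),
        (0.5, 0.005, 0.5, 100.0),
        (0.7, 0.005, 0.5, 100.0),
    )
    maxiter: int = 500
    gtol: float = 1e-6
    ftol: float = 1e-11
    # per-SNP convergence: inf-norm of the transformed-coordinate gradient
    converged_gtol: float = 1e-3


@dataclass(frozen=True)
class ModelFit:
    """MAP estimate for one SNP with convergence metadata."""

    params: ModelParams
    log_posterior: float
    n_het: int
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# expected allele fractions (the mean model)


def _tumor_mean(pi, delta, phi):
    """Expected tumor B fraction: (1-pi, pi) row vector through the
    base-calling error mixer E(delta) and the mapping-bias scaler M(phi);
    the per-sample depth scale cancels in the B-share ratio."""
    b = delta + pi * (1.0 - 2.0 * delta)
    denom = phi * b + (1.0 - phi) * (1.0 - b)
    return phi * b / denom


def expected_allele_fractions(params: ModelParams) -> ExpectedAllocation:
    """Expected tumor and normal B-allele fractions.

    The tumor mean pushes (1-pi, pi) through the error-mixing matrix
    [[1-delta, delta], [delta, 1-delta]] and the bias matrix
    diag(2(1-phi), 2phi), then takes the B share; the normal mean does the
    same starting from (0.5, 0.5), which collapses to phi exactly.
    The overall depth scale k cancels in the ratio.
    """
    p_t = float(_tumor_mean(params.pi, params.delta, params.phi))
    p_n = float(params.phi)
    if not (0.0 < p_t < 1.0) or not (0.0 < p_n < 1.0):
        raise ValueError(
            f"degenerate expected fraction (p_tumor={p_t}, p_normal={p_n}); "
            "parameters must keep both fractions strictly inside (0, 1)"
        )
    return ExpectedAllocation(p_tumor=p_t, p_normal=p_n)


# ---------------------------------------------------------------------------
# beta-binomial mass (mean-precision parameterization)


def betabinom_logpmf(k, n, p, theta):
    """Log beta-binomial mass with mean ``p`` and precision ``theta``.

    Shape parameters are alpha = p*theta, beta = (1-p)*theta, so ``p`` is the
    mean of the beta prior on the per-read success probability and ``theta``
    controls overdispersion (theta -> inf recovers the binomial).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("p must be strictly inside (0, 1)")
    if np.any(theta <= 0.0):
        raise ValueError("theta must be positive")
    a = p * theta
    b = (1.0 - p) * theta
    out = (
        gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# likelihood and posterior (scalar, per-SNP API)


def _as_count_arrays(counts_i) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """counts_i: mapping or tuple of per-het-sample count vectors
    (tumor_a, tumor_b, normal_a, normal_b)."""
    if isinstance(counts_i, dict):
        vals = (counts_i["tumor_a"], counts_i["tumor_b"],
                counts_i["normal_a"], counts_i["normal_b"])
    else:
        vals = tuple(counts_i)
    ta, tb, na, nb = (np.asarray(v, dtype=np.int64) for v in vals)
    if not (ta.shape == tb.shape == na.shape == nb.shape):
        raise ValueError("count vectors must share one shape")
    if np.any(ta < 0) or np.any(tb < 0) or np.any(na < 0) or np.any(nb < 0):
        raise ValueError("counts must be non-negative")
    return ta, tb, na, nb


def log_likelihood(counts_i, params: ModelParams) -> float:
    """Joint log-likelihood of tumor and normal counts at one SNP.

    Product over heterozygous samples of a tumor beta-binomial term (A-side
    mean 1 - p_tumor) and a normal term (A-side mean 1 - p_normal), each
    conditional on the observed total depth. Empty sample set gives 0 (the
    log of an empty product); the fit layer flags such SNPs.
    """
    ta, tb, na, nb = _as_count_arrays(counts_i)
    if ta.size == 0:
        return 0.0
    frac = expected_allele_fractions(params)
    tumor = betabinom_logpmf(tb, ta + tb, frac.p_tumor, params.theta)
    normal = betabinom_logpmf(nb, na + nb, frac.p_normal, params.theta)
    return float(np.sum(tumor) + np.sum(normal))


def log_posterior(params: ModelParams, counts_i, priors: Priors | None = None) -> float:
    """Unnormalized log posterior: log-likelihood plus independent log priors."""
    priors = priors or Priors()
    lp = priors.log_density(params)
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(counts_i, params) + lp


# ---------------------------------------------------------------------------
# transformed coordinates


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * t))


def _to_natural(t: np.ndarray, los: np.ndarray, his: np.ndarray,
                logs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained coords (m, 4) to natural parameters and return
    (values, dvalue/dt) for the chain rule."""
    s = _sigmoid(t)
    span = his - los
    lin = los + span * s
    dlin = span * s * (1.0 - s)
    if np.any(logs):
        loglin = np.exp(np.log(los) + (np.log(his) - np.log(los)) * s)
        dloglin = loglin * (np.log(his) - np.log(los)) * s * (1.0 - s)
        lin = np.where(logs, loglin, lin)
        dlin = np.where(logs, dloglin, dlin)
    return lin, dlin


def _to_unconstrained(x: np.ndarray, los: np.ndarray, his: np.ndarray,
                      logs: np.ndarray) -> np.ndarray:
    u = np.where(logs,
                 (np.log(x) - np.log(los)) / (np.log(his) - np.log(los)),
                 (x - los) / (his - los))
    u = np.clip(u, 1e-9, 1.0 - 1e-9)
    return np.log(u / (1.0 - u))


# ---------------------------------------------------------------------------
# batched objective with analytic gradient


def _batch_neg_logpost_and_grad(tflat, tb, tn, nb, nn, mask, n_het, priors):
    """Negative log posterior (constants dropped) summed over a batch of SNPs,
    plus its gradient in the transformed coordinates.

    Arrays are (m, s): tumor B count / total, normal B count / total, and a
    0/1 heterozygosity mask. The binomial coefficient term is constant in the
    parameters and omitted here; reported log posteriors are recomputed with
    the full mass at the optimum.
    """
    m = tb.shape[0]
    specs = priors.specs()
    los = np.array([s.lower for s in specs])
    his = np.array([s.upper for s in specs])
    logs = np.array([s.log_scale for s in specs])

    t = tflat.reshape(m, 4)
    x, dx_dt = _to_natural(t, los, his, logs)
    pi, delta, phi, theta = x.T
    th = theta[:, None]

    # tumor mean and its partials
    bmix = delta + pi * (1.0 - 2.0 * delta)
    denom = phi * bmix + (1.0 - phi) * (1.0 - bmix)
    p = phi * bmix / denom
    dp_db = phi * (1.0 - phi) / denom**2
    dp_dpi = dp_db * (1.0 - 2.0 * delta)
    dp_ddelta = dp_db * (1.0 - 2.0 * pi)
    dp_dphi = bmix * (1.0 - bmix) / denom**2

    total_f = 0.0
    grad_nat = np.zeros((m, 4))

    for which, (kk, ntot, pv) in enumerate(
        ((tb, tn, p), (nb, nn, phi))
    ):
        a = pv[:, None] * th
        b = (1.0 - pv)[:, None] * th
        ka = kk + a
        nkb = ntot - kk + b
        nab = ntot + th  # n + alpha + beta

        ll_entries = gammaln(ka) + gammaln(nkb) - gammaln(nab)
        per_snp = gammaln(th[:, 0]) - gammaln(a[:, 0]) - gammaln(b[:, 0])
        total_f += float(np.sum(ll_entries * mask)) + float(np.dot(n_het, per_snp))

        s_alpha = (np.sum(psi(ka) * mask, axis=1)
                   - np.sum(psi(nab) * mask, axis=1)
                   + n_het * (psi(th[:, 0]) - psi(a[:, 0])))
        s_beta = (np.sum(psi(nkb) * mask, axis=1)
                  - np.sum(psi(nab) * mask, axis=1)
                  + n_het * (psi(th[:, 0]) - psi(b[:, 0])))
        dll_dp = theta * (s_alpha - s_beta)
        dll_dth = pv * s_alpha + (1.0 - pv) * s_beta
        if which == 0:  # tumor: p depends on pi, delta, phi
            grad_nat[:, 0] += dll_dp * dp_dpi
            grad_nat[:, 1] += dll_dp * dp_ddelta
            grad_nat[:, 2] += dll_dp * dp_dphi
        else:  # normal: mean is phi itself
            grad_nat[:, 2] += dll_dp
        grad_nat[:, 3] += dll_dth

    for d, spec in enumerate(specs):
        total_f += float(np.sum(spec.log_density(x[:, d])))
        grad_nat[:, d] += spec.dlog_density(x[:, d])

    grad_t = grad_nat * dx_dt
    return -total_f, (-grad_t).ravel()


def fit_map_batch(
    tumor_a: np.ndarray,
    tumor_b: np.ndarray,
    normal_a: np.ndarray,
    normal_b: np.ndarray,
    het_mask: np.ndarray,
    priors: Priors | None = None,
    options: FitOptions | None = None,
    warm_start: np.ndarray | None = None,
    use_multistart: bool = True,
) -> dict[str, np.ndarray]:
    """MAP-fit every row (SNP) of a count batch simultaneously.

    The log posterior is separable across SNPs, so one bounded quasi-Newton
    run over the stacked transformed coordinates optimizes all rows at once;
    the multi-start is resolved per SNP by keeping the best objective (ties
    broken toward pi closest to 0.5).

    Returns arrays: params (m, 4), log_posterior (m,), converged (m,),
    n_het (m,), n_iter (scalar per start, max over starts).
    """
    priors = priors or Priors()
    options = options or FitOptions()
    tumor_a = np.asarray(tumor_a, dtype=float)
    tumor_b = np.asarray(tumor_b, dtype=float)
    normal_a = np.asarray(normal_a, dtype=float)
    normal_b = np.asarray(normal_b, dtype=float)
    mask = np.asarray(het_mask, dtype=float)
    m = tumor_a.shape[0]
    n_het = mask.sum(axis=1)

    tn = tumor_a + tumor_b
    nn = normal_a + normal_b
    # masked entries must still be numerically safe for gammaln/psi
    tb = np.where(mask > 0, tumor_b, 0.0)
    tn = np.where(mask > 0, tn, 1.0)
    nb = np.where(mask > 0, normal_b, 0.0)
    nn = np.where(mask > 0, nn, 1.0)

    specs = priors.specs()
    los = np.array([s.lower for s in specs])
    his = np.array([s.upper for s in specs])
    logs = np.array([s.log_scale for s in specs])

    start_list: list[np.ndarray] = []
    if warm_start is not None:
        ws = np.asarray(warm_start, dtype=float)
        if ws.shape != (m, 4):
            raise ValueError("warm_start must have shape (m, 4)")
        start_list.append(_to_unconstrained(
            np.clip(ws, los * (1 + 1e-9) + 1e-12, his * (1 - 1e-9)), los, his, logs))
    if use_multistart or not start_list:
        for s0 in options.starts:
            x0 = np.tile(np.asarray(s0, dtype=float), (m, 1))
            start_list.append(_to_unconstrained(x0, los, his, logs))

    args = (tb, tn, nb, nn, mask, n_het, priors)
    best_f = np.full(m, np.inf)
    best_t = np.zeros((m, 4))
    best_pi_dist = np.full(m, np.inf)
    best_grad = np.full(m, np.inf)
    max_iter_used = 0

    for t0 in start_list:
        res = optimize.minimize(
            _batch_neg_logpost_and_grad, t0.ravel(), args=args,
            method="L-BFGS-B", jac=True,
            options={"maxiter": options.maxiter, "gtol": options.gtol,
                     "ftol": options.ftol},
        )
        max_iter_used = max(max_iter_used, int(res.nit))
        t_hat = res.x.reshape(m, 4)
        # per-SNP objective and gradient at this start's optimum
        f_each = np.empty(m)
        g_norm = np.empty(m)
        _, g = _batch_neg_logpost_and_grad(res.x, *args)
        g = g.reshape(m, 4)
        g_norm = np.abs(g).max(axis=1)
        f_each = _per_snp_neg_logpost(t_hat, args)
        x_hat, _ = _to_natural(t_hat, los, his, logs)
        pi_dist = np.abs(x_hat[:, 0] - 0.5)
        tie = np.abs(f_each - best_f) <= 1e-6 * (1.0 + np.abs(best_f))
        better = (f_each < best_f) & ~tie
        prefer = better | (tie & (pi_dist < best_pi_dist))
        best_f = np.where(prefer, f_each, best_f)
        best_pi_dist = np.where(prefer, pi_dist, best_pi_dist)
        best_grad = np.where(prefer, g_norm, best_grad)
        best_t = np.where(prefer[:, None], t_hat, best_t)

    x_best, _ = _to_natural(best_t, los, his, logs)
    # report the true log posterior (binomial coefficients included)
    const = _binom_coeff_sum(tb, tn, mask) + _binom_coeff_sum(nb, nn, mask)
    log_post = -best_f + const
    converged = (best_grad < options.converged_gtol * (1.0 + np.abs(best_f))) & (n_het >= 1)
    return {
        "params": x_best,
        "log_posterior": log_post,
        "converged": converged,
        "n_het": n_het.astype(int),
        "n_iter": max_iter_used,
    }


def _per_snp_neg_logpost(t_hat: np.ndarray, args) -> np.ndarray:
    """Per-SNP negative log posterior (constants dropped) at stacked coords."""
    tb, tn, nb, nn, mask, n_het, priors = args
    specs = priors.specs()
    los = np.array([s.lower for s in specs])
    his = np.array([s.upper for s in specs])
    logs = np.array([s.log_scale for s in specs])
    x, _ = _to_natural(t_hat, los, his, logs)
    pi, delta, phi, theta = x.T
    p = _tumor_mean(pi, delta, phi)
    th = theta[:, None]
    out = np.zeros(t_hat.shape[0])
    for kk, ntot, pv in ((tb, tn, p), (nb, nn, phi)):
        a = pv[:, None] * th
        b = (1.0 - pv)[:, None] * th
        entries = gammaln(kk + a) + gammaln(ntot - kk + b) - gammaln(ntot + th)
        out += np.sum(entries * mask, axis=1)
        out += n_het * (gammaln(th[:, 0]) - gammaln(a[:, 0]) - gammaln(b[:, 0]))
    for d, spec in enumerate(specs):
        out += spec.log_density(x[:, d])
    return -out


def _binom_coeff_sum(k: np.ndarray, n: np.ndarray, mask: np.ndarray) -> np.ndarray:
    c = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return np.sum(c * mask, axis=1)


def fit_map(counts_i, priors: Priors | None = None,
            options: FitOptions | None = None) -> ModelFit:
    """MAP fit for a single SNP from its per-het-sample count vectors."""
    ta, tb, na, nb = _as_count_arrays(counts_i)
    if ta.size == 0:
        raise ValueError("fit_map requires at least one heterozygous sample")
    mask = np.ones((1, ta.size))
    res = fit_map_batch(ta[None, :], tb[None, :], na[None, :], nb[None, :],
                        mask, priors=priors, options=options)
    pi, delta, phi, theta = res["params"][0]
    return ModelFit(
        params=ModelParams(pi=float(pi), delta=float(delta), phi=float(phi),
                           theta=float(theta)),
        log_posterior=float(res["log_posterior"][0]),
        n_het=int(res["n_het"][0]),
        converged=bool(res["converged"][0]),
        n_iter=int(res["n_iter"]),
    )


def fit_cohort(cohort, priors: Priors | None = None,
               options: FitOptions | None = None,
               warm_start: np.ndarray | None = None,
               use_multistart: bool = True):
    """Fit the model at every locus of a CohortCounts; returns a DataFrame
    in the fit-results dialect (snp_id, pi_hat, ..., converged)."""
    import pandas as pd

    res = fit_map_batch(
        cohort.tumor_a, cohort.tumor_b, cohort.normal_a, cohort.normal_b,
        cohort.is_het, priors=priors, options=options,
        warm_start=warm_start, use_multistart=use_multistart,
    )
    params = res["params"]
    return pd.DataFrame({
        "snp_id": cohort.loci["snp_id"].to_numpy(),
        "pi_hat": params[:, 0],
        "delta_hat": params[:, 1],
        "phi_hat": params[:, 2],
        "theta_hat": params[:, 3],
        "n_het": res["n_het"],
        "log_posterior": res["log_posterior"],
        "converged": res["converged"],
    })
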