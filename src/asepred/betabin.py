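"""Beta-binomial likelihood for cohort allelic read counts.

At a heterozygous locus the alternative-allele read count ``k`` out of
``n`` total reads is modelled as beta-binomial with mean allele fraction
``pi`` and overdispersion ``rho``.  The mean/overdispersion
parameterisation ``alpha = pi * (1 - rho) / rho`` and
``beta = (1 - pi) * (1 - rho) / rho`` is used throughout, so the balanced
null hypothesis is the single-parameter constraint ``pi = 0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, minimize
from scipy.special import gammaln

PARAM_LO = 1e-6
PARAM_HI = 1.0 - 1e-6


class BetaBinDomainError(ValueError):
    """A parameter lies on or outside the open unit interval."""


class BetaBinDataError(ValueError):
    """A count record is inconsistent (k > n or negative)."""


def _check_params(pi: float, rho: float) -> None:
    if not (0.0 < pi < 1.0):
        raise BetaBinDomainError(f"pi={pi} must lie strictly inside (0, 1)")
    if not (0.0 < rho < 1.0):
        raise BetaBinDomainError(f"rho={rho} must lie strictly inside (0, 1)")


def ab_from_mean_overdispersion(pi: float, rho: float) -> tuple[float, float]:
    """Map (mean, overdispersion) to the classical (alpha, beta)."""
    _check_params(pi, rho)
    scale = (1.0 - rho) / rho
    return pi * scale, (1.0 - pi) * scale


def betabin_logpmf(k, n, pi: float, rho: float):
    """Log PMF of the beta-binomial, vectorised over (k, n).

    Computed with log-gamma functions:
    ``log C(n, k) + log B(k + a, n - k + b) - log B(a, b)``.
    """
    a, b = ab_from_mean_overdispersion(pi, rho)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k < 0) or np.any(n < k):
        bad = np.argwhere((k < 0) | (n < k)).ravel()
        raise BetaBinDataError(f"invalid count record(s) at index {bad.tolist()}: need 0 <= k <= n")
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def betabin_loglik(counts, pi: float, rho: float) -> float:
    """Total log-likelihood of ``counts`` = iterable of (k, n) pairs.

    An empty collection has log-likelihood 0 by the empty-sum convention.
    """
    counts = list(counts)
    if not counts:
        _check_params(pi, rho)
        return 0.0
    k = np.array([c[0] for c in counts], dtype=float)
    n = np.array([c[1] for c in counts], dtype=float)
    return float(np.sum(betabin_logpmf(k, n, pi, rho)))


def sample_betabin(n, pi: float, rho: float, rng: np.random.Generator):
    """Draw beta-binomial counts: p ~ Beta(a, b) then k ~ Binomial(n, p)."""
    a, b = ab_from_mean_overdispersion(pi, rho)
    n = np.asarray(n)
    p = rng.beta(a, b, size=n.shape)
    return rng.binomial(n, p)


@dataclass
class BetaBinFit:
    """Maximum-likelihood fit of the beta-binomial at one locus."""

    pi_hat: float
    rho_hat: float
    loglik: float
    converged: bool
    n_individuals: int


def _moment_start(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Moment-based starting values (pooled fraction; dispersion of p_i)."""
    pi0 = float(np.clip(k.sum() / n.sum(), 0.01, 0.99))
    p = k / n
    v = float(np.var(p))
    denom = pi0 * (1.0 - pi0)
    m = float(np.mean(1.0 / n))
    if denom > 0 and m < 1.0:
        rho0 = (v - denom * m) / (denom * (1.0 - m))
    else:
        rho0 = 0.01
    rho0 = float(np.clip(rho0, 1e-4, 0.5))
    return pi0, rho0


def _projected_grad_small(res, bounds, tol: float = 1e-2) -> bool:
    """Accept a line-search abort that still sits at a stationary point.

    L-BFGS-B occasionally reports abnormal termination when successive
    steps fall below float precision right at the optimum; the projected
    gradient (zeroed where it points outward at an active bound) decides
    whether the point is genuinely stationary.
    """
    g = np.atleast_1d(np.asarray(res.jac, dtype=float)).copy()
    x = np.atleast_1d(res.x)
    lo, hi = bounds
    at_lo = np.isclose(x, lo)
    at_hi = np.isclose(x, hi)
    g[at_lo & (g > 0)] = 0.0
    g[at_hi & (g < 0)] = 0.0
    return bool(np.max(np.abs(g)) < tol)


def fit_locus(counts, fix_pi: float | None = None, n_restarts: int = 2,
              seed: int = 0) -> BetaBinFit:
    """Maximise the beta-binomial log-likelihood for one locus.

    Parameters are bounded to ``[1e-6, 1 - 1e-6]``.  When ``fix_pi`` is
    given only the overdispersion is free (the balanced-null fit).  On
    optimizer failure up to ``n_restarts`` random restarts are attempted;
    if all fail the best point found is returned with ``converged=False``.
    """
    counts = list(counts)
    if not counts:
        raise BetaBinDataError("fit_locus requires at least one (k, n) record")
    if fix_pi is not None and not (0.0 < fix_pi < 1.0):
        raise BetaBinDomainError(f"fix_pi={fix_pi} must lie strictly inside (0, 1)")
    k = np.array([c[0] for c in counts], dtype=float)
    n = np.array([c[1] for c in counts], dtype=float)
    if np.any(k < 0) or np.any(n < k) or np.any(n < 1):
        raise BetaBinDataError("counts must satisfy 0 <= k <= n and n >= 1")

    pi0, rho0 = _moment_start(k, n)
    bounds = (PARAM_LO, PARAM_HI)

    def nll_free(theta):
        return -float(np.sum(betabin_logpmf(k, n, theta[0], theta[1])))

    def nll_rho(rho):
        return -float(np.sum(betabin_logpmf(k, n, fix_pi, rho)))

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    if fix_pi is None:
        starts = [(pi0, rho0)]
        for _ in range(n_restarts):
            starts.append((rng.uniform(0.05, 0.95), rng.uniform(1e-4, 0.5)))
        for i, x0 in enumerate(starts):
            res = minimize(nll_free, x0=np.array(x0), method="L-BFGS-B",
                           bounds=[bounds, bounds],
                           options={"ftol": 1e-11, "gtol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
            if res.success or _projected_grad_small(res, bounds):
                converged = True
                if i == 0:
                    break
        if not converged:
            # line-search aborts can still sit at the optimum; accept if a
            # derivative-free polish cannot improve the point meaningfully
            def nll_clipped(theta):
                return nll_free(np.clip(theta, PARAM_LO, PARAM_HI))

            polish = minimize(nll_clipped, x0=best.x, method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
            improved = best.fun - polish.fun
            if polish.fun < best.fun:
                best = polish
                best.x = np.clip(polish.x, PARAM_LO, PARAM_HI)
            converged = bool(polish.success) or improved < 1e-4
        pi_hat, rho_hat = float(best.x[0]), float(best.x[1])
    else:
        res = minimize_scalar(nll_rho, bounds=bounds, method="bounded",
                              options={"xatol": 1e-10})
        best = res
        converged = bool(res.success)
        pi_hat, rho_hat = float(fix_pi), float(res.x)

    return BetaBinFit(pi_hat=pi_hat, rho_hat=rho_hat, loglik=-float(best.fun),
                      converged=converged, n_individuals=len(counts))
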