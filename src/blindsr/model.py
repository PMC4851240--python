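"""Conditional type I error of the two-stage z-test and the worst-case rule.

Notation.  Stage 1 observes ``n1`` subjects, stage 2 another ``n2``; the final
statistic is ``Z_N = (sigma * sqrt(N))^-1 * sum (2 G_i - 1) X_i`` with
``N = n1 + n2``, rejected when it exceeds ``z_{1-alpha}``.  Writing
``u = sqrt(n1 / N)``, the conditional rejection probability given a normal
approximation ``Z1 | blinded data ~ N(m1, V1)`` is

    1 - Phi( (z_{1-alpha} - u * m1) / sqrt((1 - u^2) + V1 * u^2) ),

which every function below evaluates in terms of ``u``.  The worst-case rule
maximizes this over ``n2 in [n2min, n2max]``; by differentiation in ``u`` the
maximizer is one of: the two interval endpoints, or (only when ``V1 < 1`` and
``m1 > 0``) the interior stationary point

    u* = m1 / (z_{1-alpha} * (1 - V1)),   i.e.
    n2* = n1 * [ (z_{1-alpha} (1 - V1) / m1)^2 - 1 ],

clamped to the interval.  Evaluating the conditional error at this finite
candidate set is the exact closed form (no grid search).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .params import (
    ConditionalLaw,
    EndpointParams,
    ReassessmentDecision,
    Stage1Data,
    TrialDesign,
    UNBOUNDED,
)

__all__ = [
    "z_statistic",
    "allocation_posterior",
    "conditional_moments",
    "conditional_error_unblinded",
    "conditional_error_blinded",
    "worst_case_n2",
    "stage1_effect_estimates",
]


def z_quantile(alpha: float) -> float:
    """Upper one-sided critical value z_{1-alpha} of the standard normal."""
    return float(ndtri(1.0 - alpha))


def z_statistic(x, g, sigma: float) -> float:
    """First-stage (or full-trial) z-statistic (sigma known).

    ``(sigma * sqrt(N))^-1 * sum_i (2 g_i - 1) x_i`` over the N supplied
    subjects; relabelling the arms (g -> 1-g) negates the result.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g)
    if x.shape != g.shape or x.ndim != 1:
        raise ValueError("x and g must be 1-d arrays of equal length")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    return float(np.sum((2 * g - 1) * x) / (sigma * np.sqrt(x.size)))


def log_likelihood_ratio(x, y, params: EndpointParams):
    """Log f(x,y | treatment) - log f(x,y | control) for the bivariate model.

    Because both arms share the covariance matrix, the ratio is linear in
    (x, y).  For |rho| = 1 the densities are singular; the ratio is then the
    exact limit: +/-inf according to which arm's line the observation lies
    nearer to (0 on ties), so that ``expit`` of it is the 0/1/0.5 indicator.
    Vectorized over x, y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s, r = params.sigma, params.rho
    if abs(r) == 1.0:
        sgn = 1.0 if r > 0 else -1.0
        # residual of the deterministic relation y = nu_g + sgn*(x - mu_g)
        r1 = np.abs((y - params.nu1) - sgn * (x - params.mu1))
        r0 = np.abs((y - params.nu0) - sgn * (x - params.mu0))
        return np.where(r1 < r0, np.inf, np.where(r1 > r0, -np.inf, 0.0))
    a = (x - 0.5 * (params.mu0 + params.mu1)) / s
    b = (y - 0.5 * (params.nu0 + params.nu1)) / s
    dx = (params.mu1 - params.mu0) / s
    dy = (params.nu1 - params.nu0) / s
    return (dx * (a - r * b) + dy * (b - r * a)) / (1.0 - r * r)


def allocation_posterior(x, y, params: EndpointParams):
    """Posterior probability q that a subject received treatment.

    Under simple randomization (prior 1/2 per subject, independent), Bayes'
    theorem gives ``q = phi_1(x,y) / (phi_0(x,y) + phi_1(x,y))`` with
    ``phi_g`` the bivariate normal density of arm g.  Returns a scalar for
    scalar input, an array otherwise; values in [0, 1].
    """
    q = expit(log_likelihood_ratio(x, y, params))
    return float(q) if np.isscalar(x) or np.ndim(x) == 0 else q


def conditional_moments(data: Stage1Data, q, sigma: float) -> ConditionalLaw:
    """Asymptotic mean/variance of Z1 given blinded data (simple randomization).

    m1 = sum (2 q_i - 1) x_i / (sigma sqrt(n1));
    V1 = 4 sum x_i^2 q_i (1 - q_i) / (sigma^2 n1).
    """
    q = np.asarray(q, dtype=float)
    if q.shape != data.x.shape:
        raise ValueError("q must match data length")
    if data.n1 == 0:
        raise ValueError("empty stage-1 data")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    x = data.x
    m1 = float(np.sum((2 * q - 1) * x) / (sigma * np.sqrt(data.n1)))
    v1 = float(4.0 * np.sum(x * x * q * (1 - q)) / (sigma**2 * data.n1))
    return ConditionalLaw(mean=m1, variance=max(v1, 0.0))


def _ce_at_u(u, mean, variance, z):
    """Conditional error at information fraction u = sqrt(n1/N); vectorized.

    The denominator (1-u^2) + V*u^2 is the nonnegative-by-construction form
    of (n1*V + n2)/N; it vanishes only at u=1 (n2=0) with V=0, where the
    conditional error degenerates to the threshold indicator 1{mean > z}
    (0.5 on the boundary).
    """
    u = np.asarray(u, dtype=float)
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    d2 = (1.0 - u * u) + variance * u * u
    degen = d2 <= 0.0
    safe = np.where(degen, 1.0, d2)
    arg = (z - mean * u) / np.sqrt(safe)
    ce = 1.0 - ndtr(arg)
    if np.any(degen):
        thresh = np.where(mean > z, 1.0, np.where(mean < z, 0.0, 0.5))
        ce = np.where(degen, np.broadcast_to(thresh, ce.shape), ce)
    return ce


def _u_of_n2(n1, n2):
    """Information fraction sqrt(n1/N); 0 when n2 is the unbounded sentinel."""
    n2 = np.asarray(n2, dtype=float)
    finite = np.where(np.isinf(n2), 0.0, n2)
    return np.where(np.isinf(n2), 0.0, np.sqrt(n1 / (n1 + finite)))


def conditional_error_unblinded(z1, n1, n2, alpha: float):
    """Conditional rejection probability given the unblinded stage-1 statistic.

    1 - Phi( sqrt(N/n2) z_{1-alpha} - sqrt(n1/n2) z1 ), N = n1 + n2.  The
    n2 = 0 limit is the indicator 1{z1 > z_{1-alpha}}; the n2 -> inf limit is
    alpha.  Strictly increasing in z1.  Vectorized over z1 and n2.
    """
    if np.any(np.asarray(n1) <= 0):
        raise ValueError("n1 must be > 0")
    if np.any(np.asarray(n2) < 0):
        raise ValueError("n2 must be >= 0")
    z = z_quantile(alpha)
    out = _ce_at_u(_u_of_n2(n1, n2), z1, 0.0, z)
    return float(out) if out.ndim == 0 else out


def conditional_error_blinded(law: ConditionalLaw, n1, n2, alpha: float):
    """Conditional rejection probability given only the blinded stage-1 data.

    Evaluates 1 - Phi( (z_{1-alpha} - sqrt(n1/N) m1) / sqrt((n1 V1 + n2)/N) )
    under the normal approximation Z1 | data ~ N(m1, V1).  With V1 = 0 it
    coincides with :func:`conditional_error_unblinded` at z1 = m1.
    """
    z = z_quantile(alpha)
    out = _ce_at_u(_u_of_n2(n1, n2), law.mean, law.variance, z)
    return float(out) if out.ndim == 0 else out


def _worst_case_arrays(mean, variance, n1, n2min, n2max, alpha):
    """Vectorized worst-case rule; returns (n2, conditional_error) arrays.

    Candidate set: u_hi (n2min), the clamped interior stationary point where
    V < 1 and m > 0, and u_lo (n2max, u=0 when unbounded).  Ties prefer the
    smaller n2 (candidates are scanned in that order).
    """
    mean, variance = np.broadcast_arrays(
        np.asarray(mean, dtype=float), np.asarray(variance, dtype=float)
    )
    z = z_quantile(alpha)
    u_lo = 0.0 if np.isinf(n2max) else np.sqrt(n1 / (n1 + n2max))
    u_hi = np.sqrt(n1 / (n1 + n2min))
    a = 1.0 - variance
    with np.errstate(divide="ignore", invalid="ignore"):
        u_star = np.where((a > 0) & (mean > 0), mean / (a * z), u_lo)
    u_star = np.clip(u_star, u_lo, u_hi)
    cand = np.stack(
        [np.broadcast_to(u_hi, mean.shape), u_star, np.broadcast_to(u_lo, mean.shape)]
    )
    ce = _ce_at_u(cand, mean[None, ...], variance[None, ...], z)
    best = np.argmax(ce, axis=0)
    u_best = np.take_along_axis(cand, best[None, ...], axis=0)[0]
    ce_best = np.take_along_axis(ce, best[None, ...], axis=0)[0]
    with np.errstate(divide="ignore"):
        n2 = np.where(u_best > 0, n1 * (1.0 / (u_best * u_best) - 1.0), np.inf)
    # snap endpoint candidates to the exact bounds (floating-point round trip)
    n2 = np.where(u_best == u_hi, n2min, n2)
    if not np.isinf(n2max):
        n2 = np.where(u_best == u_lo, n2max, n2)
    return n2, ce_best


def worst_case_n2(law: ConditionalLaw, design: TrialDesign) -> ReassessmentDecision:
    """Second-stage size maximizing the blinded conditional error.

    Closed form: the maximizer over ``[n2min, n2max]`` is either a bound or,
    when ``V1 < 1`` and ``m1 > 0``, the interior point
    ``n2* = n1 [ (z_{1-alpha}(1-V1)/m1)^2 - 1 ]`` clamped to the bounds.  With
    ``n2max`` unbounded and the rule selecting the unbounded branch, ``n2`` is
    returned as ``math.inf`` and the conditional error is the limit ``alpha``.
    """
    n2, ce = _worst_case_arrays(
        law.mean, law.variance, design.n1, design.n2min, design.n2max, design.alpha
    )
    return ReassessmentDecision(n2=float(n2), conditional_error=float(ce))


def stage1_effect_estimates(data: Stage1Data, q=None):
    """Unblinded and blinded first-stage effect estimates.

    ``xbar  = sum 2 (2 g_i - 1) x_i / n1`` (requires the true allocation g);
    ``xbar_b = sum 2 (2 q_i - 1) x_i / n1`` (its blinded reconstruction).
    The correlation of the two across trials measures unblinding.
    Returns ``(xbar, xbar_b)``; each is None when its input is missing.
    """
    xbar = xbar_b = None
    if data.g is not None:
        xbar = float(np.sum(2.0 * (2 * data.g - 1) * data.x) / data.n1)
    if q is not None:
        q = np.asarray(q, dtype=float)
        xbar_b = float(np.sum(2.0 * (2 * q - 1) * data.x) / data.n1)
    if xbar is None and xbar_b is None:
        raise ValueError("need the true allocation g and/or posterior q")
    return xbar, xbar_b
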