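"""Monte Carlo drivers: maximum type I error and the unblinding correlation.

Every driver simulates stage-1 trials from the bivariate-normal model,
applies the worst-case blinded reassessment rule and aggregates either the
analytic conditional error (fast, the primary quantity) or a full-trial
rejection indicator (z- or t-test at the final analysis).  All computation is
vectorized across simulation runs; a master seed spawns independent
substreams per chunk of runs so results are reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as t_dist

from .blocks import block_llr_scores, enumerate_block_allocations
from .model import _ce_at_u, _u_of_n2, _worst_case_arrays, log_likelihood_ratio, z_quantile
from .params import EndpointParams, SimulationConfig, Stage1Data, TrialDesign, UNBOUNDED

__all__ = [
    "SimulationResult",
    "LYMPHOCYTE",
    "WBC",
    "case_study_params",
    "estimate_max_type1_analytic",
    "estimate_max_type1_montecarlo",
    "mismatched_rule_study",
    "unblinding_correlation",
    "run_case_study",
    "run_unblinding_study",
    "run_effectsize_sweep",
    "run_block_study",
]

# Fingolimod case-study secondary-endpoint presets (units: 1e9 cells/L).
LYMPHOCYTE = {"nu0": 1.8, "nu1": 0.55, "sigma": 0.31}
WBC = {"nu0": 6.5, "nu1": 3.8, "sigma": 1.57}

_CHUNK_ELEMS = 2_000_000  # target elements per simulation chunk
_UNBOUNDED_CAP_FACTOR = 100  # realized n2 cap (in units of n1) for full-trial MC


@dataclass(frozen=True)
class SimulationResult:
    """A Monte Carlo estimate with its standard error and provenance."""

    estimate: float
    mc_se: float
    n_runs: int
    seed: int
    settings: dict = field(default_factory=dict)


def case_study_params(endpoint: str, rho: float) -> EndpointParams:
    """Endpoint parameters of the case study under H0 on the primary endpoint."""
    presets = {"lymphocyte": LYMPHOCYTE, "wbc": WBC}
    if endpoint not in presets:
        raise ValueError(f"endpoint must be one of {sorted(presets)}, got {endpoint!r}")
    p = presets[endpoint]
    return EndpointParams(mu0=0.0, mu1=0.0, rho=rho, **p)


# ---------------------------------------------------------------------------
# vectorized simulation engine
# ---------------------------------------------------------------------------


def _chunk_sizes(n_runs: int, n1: int):
    chunk = max(1, _CHUNK_ELEMS // max(n1, 1))
    while n_runs > 0:
        c = min(chunk, n_runs)
        yield c
        n_runs -= c


def _draw_allocations(rng, c: int, n1: int, scheme: str, tau: Optional[int]):
    if scheme == "simple":
        return (rng.random((c, n1)) < 0.5).astype(np.int64)
    if scheme == "random_allocation":
        r = rng.random((c, n1))
        return (r.argsort(axis=1).argsort(axis=1) < n1 // 2).astype(np.int64)
    r = rng.random((c, n1 // tau, tau))
    g = (r.argsort(axis=2).argsort(axis=2) < tau // 2).astype(np.int64)
    return g.reshape(c, n1)


def _draw_chunk(rng, c: int, params: EndpointParams, n1: int, scheme: str, tau):
    g = _draw_allocations(rng, c, n1, scheme, tau)
    z1 = rng.standard_normal((c, n1))
    z2 = rng.standard_normal((c, n1))
    r = params.rho
    x = np.where(g == 1, params.mu1, params.mu0) + params.sigma * z1
    y = np.where(g == 1, params.nu1, params.nu0) + params.sigma * (
        r * z1 + np.sqrt(max(1.0 - r * r, 0.0)) * z2
    )
    return g, x, y


def _moments_chunk(x, y, params: EndpointParams, rule: str, tau: Optional[int]):
    """(m1, V1) per run for a chunk; rule 'simple' or 'block'."""
    s = params.sigma
    n1 = x.shape[1]
    if rule == "simple":
        q = expit(log_likelihood_ratio(x, y, params))
        m1 = ((2.0 * q - 1.0) * x).sum(axis=1) / (s * np.sqrt(n1))
        v1 = 4.0 * (x * x * q * (1.0 - q)).sum(axis=1) / (s * s * n1)
        return m1, np.maximum(v1, 0.0), q
    allocs = enumerate_block_allocations(tau)
    c = x.shape[0]
    xb = x.reshape(c, n1 // tau, tau)
    yb = y.reshape(c, n1 // tau, tau)
    p, scores = block_llr_scores(xb, yb, params, allocs)
    e1 = (p * scores).sum(axis=-1)
    e2 = (p * scores * scores).sum(axis=-1)
    m1 = e1.sum(axis=1) / (s * np.sqrt(n1))
    v1 = np.maximum(e2 - e1 * e1, 0.0).sum(axis=1) / (s * s * n1)
    return m1, v1, None


def _resolve_rule(config: SimulationConfig, rule: Optional[str]) -> str:
    if rule is None:
        rule = "block" if config.design.scheme == "block" else "random_allocation"
    if rule in ("simple", "random_allocation"):
        return "simple"  # the per-subject-posterior rule of the unblocked case
    if rule == "block":
        if config.design.scheme != "block":
            raise ValueError("block rule requires a block-randomized design")
        return "block"
    raise ValueError(f"unknown rule {rule!r}")


def estimate_max_type1_analytic(
    config: SimulationConfig,
    rule: Optional[str] = None,
    fixed_n2: Optional[float] = None,
) -> SimulationResult:
    """Maximum type I error under the worst-case rule, analytic aggregation.

    Per run: simulate blinded stage-1 data, form the conditional law of Z1
    (per-subject posteriors, or block posteriors when ``rule='block'``),
    apply the closed-form worst-case n2 and accumulate the blinded
    conditional error.  The estimate is the mean of per-run conditional
    errors; ``mc_se`` their standard deviation over sqrt(n_runs).

    ``fixed_n2`` disables the adaptation and evaluates the conditional error
    at that second-stage size instead (the null-calibration check: under H0
    the average conditional error is then exactly alpha).
    """
    d, p = config.design, config.params
    rule = _resolve_rule(config, rule)
    z = z_quantile(d.alpha)
    sizes = list(_chunk_sizes(config.n_runs, d.n1))
    total = s1 = s2 = 0.0
    for c, child in zip(sizes, np.random.SeedSequence(config.seed).spawn(len(sizes))):
        rng = np.random.default_rng(child)
        _, x, y = _draw_chunk(rng, c, p, d.n1, d.scheme, d.tau)
        m1, v1, _ = _moments_chunk(x, y, p, rule, d.tau)
        if fixed_n2 is None:
            _, ce = _worst_case_arrays(m1, v1, d.n1, d.n2min, d.n2max, d.alpha)
        else:
            ce = _ce_at_u(_u_of_n2(d.n1, fixed_n2), m1, v1, z)
        total += c
        s1 += float(ce.sum())
        s2 += float((ce * ce).sum())
    mean = s1 / total
    var = max(s2 / total - mean * mean, 0.0)
    return SimulationResult(
        estimate=mean,
        mc_se=float(np.sqrt(var / total)),
        n_runs=config.n_runs,
        seed=config.seed,
        settings={"driver": "analytic", "rule": rule, "fixed_n2": fixed_n2},
    )


def _round_even(n2: np.ndarray) -> np.ndarray:
    return 2.0 * np.round(n2 / 2.0)


def _stage2_group_stats(rng, n_half: np.ndarray, mu: float, sigma: float):
    """Sufficient statistics of one arm's stage-2 responses, vectorized.

    For a group of size m: mean ~ N(mu, sigma^2/m), SSE ~ sigma^2 chi^2_{m-1}
    (both exact for the normal model).  m = 0 gives (0, 0) placeholders.
    """
    m = n_half.astype(float)
    mean = np.where(m > 0, mu + sigma * rng.standard_normal(m.shape) / np.sqrt(np.maximum(m, 1.0)), 0.0)
    df = np.maximum(m - 1.0, 0.0)
    sse = np.where(df > 0, sigma**2 * rng.chisquare(np.maximum(df, 1.0)), 0.0)
    return mean, sse


def estimate_max_type1_montecarlo(
    config: SimulationConfig,
    test: str = "z",
    rule: Optional[str] = None,
    fixed_n2: Optional[float] = None,
) -> SimulationResult:
    """Maximum type I error by full-trial simulation (z- or t-test).

    Per run: simulate stage 1, apply the worst-case rule with the chosen n2
    rounded to the nearest even integer and clamped to the bounds (an
    unbounded choice is capped at 100*n1), simulate the balanced second
    stage, and reject via the known-sigma z-statistic against z_{1-alpha} or
    the pooled-variance t-statistic against the t quantile with N-2 degrees
    of freedom.  The estimate is the rejection fraction (binomial mc_se).

    ``fixed_n2`` disables the adaptation and always uses that second-stage
    size (the null-calibration setting: the rejection rate is then alpha).
    """
    if test not in ("z", "t"):
        raise ValueError(f"test must be 'z' or 't', got {test!r}")
    d, p = config.design, config.params
    rule = _resolve_rule(config, rule)
    z = z_quantile(d.alpha)
    cap = _UNBOUNDED_CAP_FACTOR * d.n1
    sizes = list(_chunk_sizes(config.n_runs, d.n1))
    rejections = 0.0
    total = 0
    for c, child in zip(sizes, np.random.SeedSequence(config.seed).spawn(len(sizes))):
        rng = np.random.default_rng(child)
        g, x, y = _draw_chunk(rng, c, p, d.n1, d.scheme, d.tau)
        if fixed_n2 is None:
            m1, v1, _ = _moments_chunk(x, y, p, rule, d.tau)
            n2, _ = _worst_case_arrays(m1, v1, d.n1, d.n2min, d.n2max, d.alpha)
            n2 = np.where(np.isinf(n2), cap, n2)
            n2 = np.clip(_round_even(n2), d.n2min, min(d.n2max, cap))
        else:
            n2 = np.full(c, float(fixed_n2))
        n_tot = d.n1 + n2
        z1 = ((2 * g - 1) * x).sum(axis=1) / (p.sigma * np.sqrt(d.n1))
        if test == "z":
            dmu = p.mu1 - p.mu0
            z2 = np.sqrt(n2) * dmu / (2 * p.sigma) + rng.standard_normal(c)
            u = np.sqrt(d.n1 / n_tot)
            zn = u * z1 + np.sqrt(np.maximum(1 - u * u, 0.0)) * z2
            rej = zn > z
        else:
            rej = _t_test_reject(rng, g, x, n2, p, d.alpha)
        rejections += float(rej.sum())
        total += c
    est = rejections / total
    return SimulationResult(
        estimate=est,
        mc_se=float(np.sqrt(est * (1 - est) / total)),
        n_runs=config.n_runs,
        seed=config.seed,
        settings={"driver": "montecarlo", "test": test, "rule": rule},
    )


def _t_test_reject(rng, g, x, n2, params: EndpointParams, alpha: float):
    """Pooled-variance two-sample t-test rejection indicators, vectorized.

    Stage-2 data enter through exact per-arm sufficient statistics (group
    mean and chi-squared sum of squares) so runs with different n2 vectorize.
    """
    n1 = x.shape[1]
    n1_t = g.sum(axis=1).astype(float)
    n1_c = n1 - n1_t
    sum_t = (x * g).sum(axis=1)
    sum_c = x.sum(axis=1) - sum_t
    mean1_t = sum_t / np.maximum(n1_t, 1.0)
    mean1_c = sum_c / np.maximum(n1_c, 1.0)
    sse1 = ((x - np.where(g == 1, mean1_t[:, None], mean1_c[:, None])) ** 2).sum(axis=1)

    half2 = n2 / 2.0
    m2_t, sse2_t = _stage2_group_stats(rng, half2, params.mu1, params.sigma)
    m2_c, sse2_c = _stage2_group_stats(rng, half2, params.mu0, params.sigma)

    def combine(nA, mA, nB, mB):
        n = nA + nB
        mean = np.where(n > 0, (nA * mA + nB * mB) / np.maximum(n, 1.0), 0.0)
        cross = np.where((nA > 0) & (nB > 0), nA * nB / np.maximum(n, 1.0) * (mA - mB) ** 2, 0.0)
        return n, mean, cross

    nt, mt, cross_t = combine(n1_t, mean1_t, half2, m2_t)
    nc, mc, cross_c = combine(n1_c, mean1_c, half2, m2_c)
    sse = sse1 + sse2_t + sse2_c + cross_t + cross_c
    n_tot = nt + nc
    df = n_tot - 2
    s2 = sse / df
    tstat = (mt - mc) / np.sqrt(s2 * (1.0 / nt + 1.0 / nc))
    return tstat > t_dist.isf(alpha, df)


def mismatched_rule_study(config: SimulationConfig) -> dict:
    """Unblocked rule applied to block-randomized data, vs. random allocation.

    The design must use the block scheme.  Both arms of the comparison apply
    the per-subject (unblocked) posterior rule; only the data-generating
    randomization differs.  Returns the two analytic estimates and their
    difference.
    """
    if config.design.scheme != "block":
        raise ValueError("mismatched_rule_study requires a block-randomized design")
    blocked = estimate_max_type1_analytic(config, rule="random_allocation")
    d = config.design
    ra_design = TrialDesign(
        n1=d.n1, n2min=d.n2min, n2max=d.n2max, alpha=d.alpha, scheme="random_allocation"
    )
    ra_config = SimulationConfig(
        params=config.params, design=ra_design, n_runs=config.n_runs, seed=config.seed + 1
    )
    unblocked = estimate_max_type1_analytic(ra_config, rule="random_allocation")
    return {
        "block_data": blocked,
        "random_allocation": unblocked,
        "difference": blocked.estimate - unblocked.estimate,
    }


def unblinding_correlation(
    params: EndpointParams, n1: int, n_runs: int, seed: int = 0
) -> SimulationResult:
    """Correlation r between unblinded and blinded stage-1 effect estimates.

    Across simulated stage-1 datasets (random allocation), computes the
    Pearson correlation of Xbar = sum 2(2G-1)X / n1 with its blinded
    reconstruction Xbar_b = sum 2(2q-1)X / n1.  With an uninformative
    secondary endpoint and rho = 0, Xbar_b is degenerate and r is reported
    as 0.  mc_se is the large-sample SE (1 - r^2)/sqrt(n_runs).
    """
    sizes = list(_chunk_sizes(n_runs, n1))
    xbars = []
    xbars_b = []
    for c, child in zip(sizes, np.random.SeedSequence(seed).spawn(len(sizes))):
        rng = np.random.default_rng(child)
        g, x, y = _draw_chunk(rng, c, params, n1, "random_allocation", None)
        q = expit(log_likelihood_ratio(x, y, params))
        xbars.append((2.0 * (2 * g - 1) * x).sum(axis=1) / n1)
        xbars_b.append((2.0 * (2 * q - 1) * x).sum(axis=1) / n1)
    a = np.concatenate(xbars)
    b = np.concatenate(xbars_b)
    if np.std(b) == 0.0 or np.std(a) == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return SimulationResult(
        estimate=r,
        mc_se=float((1 - r * r) / np.sqrt(n_runs)),
        n_runs=n_runs,
        seed=seed,
        settings={"driver": "unblinding_correlation", "n1": n1},
    )


def _default_rho_grid() -> np.ndarray:
    return np.linspace(0.0, 0.9, 10)


def run_case_study(
    endpoint: str,
    restricted: bool = False,
    rho_grid=None,
    n_runs: int = 200_000,
    seed: int = 0,
    n1: int = 400,
    alpha: float = 0.025,
) -> pd.DataFrame:
    """Maximum type I error over a rho grid for a case-study parameterization.

    ``endpoint`` is ``'lymphocyte'`` or ``'wbc'``; ``restricted`` selects
    n2 in [200, 1600] instead of the unrestricted second stage.  Returns one
    row per rho with the analytic alpha_max estimate and its mc_se.
    """
    if rho_grid is None:
        rho_grid = _default_rho_grid()
    bounds = (200.0, 1600.0) if restricted else (0.0, UNBOUNDED)
    children = np.random.SeedSequence(seed).spawn(len(rho_grid))
    rows = []
    for rho, child in zip(rho_grid, children):
        design = TrialDesign(
            n1=n1, n2min=bounds[0], n2max=bounds[1], alpha=alpha,
            scheme="random_allocation",
        )
        cfg = SimulationConfig(
            params=case_study_params(endpoint, float(rho)),
            design=design,
            n_runs=n_runs,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        res = estimate_max_type1_analytic(cfg)
        rows.append(
            {"endpoint": endpoint, "rho": float(rho), "restricted": restricted,
             "estimate": res.estimate, "mc_se": res.mc_se,
             "n_runs": n_runs, "seed": seed}
        )
    return pd.DataFrame(rows)


def run_unblinding_study(
    endpoint: str,
    rho_grid=None,
    n_runs: int = 50_000,
    seed: int = 0,
    n1: int = 400,
) -> pd.DataFrame:
    """Unblinding correlation r over a rho grid for a case-study endpoint."""
    if rho_grid is None:
        rho_grid = _default_rho_grid()
    children = np.random.SeedSequence(seed).spawn(len(rho_grid))
    rows = []
    for rho, child in zip(rho_grid, children):
        res = unblinding_correlation(
            case_study_params(endpoint, float(rho)), n1, n_runs,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {"endpoint": endpoint, "rho": float(rho), "estimate": res.estimate,
             "mc_se": res.mc_se, "n_runs": n_runs, "seed": seed}
        )
    return pd.DataFrame(rows)


def run_effectsize_sweep(
    rho_list,
    effect_grid,
    design: TrialDesign,
    n_runs: int = 200_000,
    seed: int = 0,
    test: str = "analytic",
    sigma: float = 1.0,
) -> pd.DataFrame:
    """alpha_max as a function of secondary effect size, per correlation.

    ``test`` selects the aggregation: ``'analytic'`` (conditional-error
    average) or ``'z'``/``'t'`` (full-trial simulation).  Returns one row per
    (rho, effect) combination.
    """
    rows = []
    pairs = [(float(r), float(e)) for r in rho_list for e in effect_grid]
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    for (rho, effect), child in zip(pairs, children):
        params = EndpointParams(mu0=0.0, mu1=0.0, nu0=0.0, nu1=effect, sigma=sigma, rho=rho)
        cfg = SimulationConfig(
            params=params, design=design, n_runs=n_runs,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        if test == "analytic":
            res = estimate_max_type1_analytic(cfg)
        else:
            res = estimate_max_type1_montecarlo(cfg, test=test)
        rows.append(
            {"rho": rho, "effect": effect, "test": test, "estimate": res.estimate,
             "mc_se": res.mc_se, "n_runs": n_runs, "seed": seed}
        )
    return pd.DataFrame(rows)


def run_block_study(
    tau_list,
    design: TrialDesign,
    effect: float,
    rho: float = 0.0,
    n_runs: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """alpha_max under block randomization with the block-informed rule.

    One row per block length tau (plus the unblocked reference as tau = 0).
    """
    rows = []
    entries = [int(t) for t in tau_list] + [0]
    children = np.random.SeedSequence(seed).spawn(len(entries))
    for tau, child in zip(entries, children):
        if tau:
            d = TrialDesign(
                n1=design.n1, n2min=design.n2min, n2max=design.n2max,
                alpha=design.alpha, scheme="block", tau=tau,
            )
            rule = "block"
        else:
            d = TrialDesign(
                n1=design.n1, n2min=design.n2min, n2max=design.n2max,
                alpha=design.alpha, scheme="random_allocation",
            )
            rule = "random_allocation"
        params = EndpointParams(mu0=0.0, mu1=0.0, nu0=0.0, nu1=effect, sigma=1.0, rho=rho)
        cfg = SimulationConfig(
            params=params, design=d, n_runs=n_runs,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        res = estimate_max_type1_analytic(cfg, rule=rule)
        rows.append(
            {"tau": tau, "rho": rho, "effect": effect, "estimate": res.estimate,
             "mc_se": res.mc_se, "n_runs": n_runs, "seed": seed}
        )
    return pd.DataFrame(rows)
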