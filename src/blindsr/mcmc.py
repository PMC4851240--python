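"""Conditional error under random allocation via enumeration or MCMC.

Under random allocation all C(n1, n1/2) balanced assignment vectors are a
priori equally likely, so the posterior given the blinded data is
proportional to the product of per-subject densities.  Exact enumeration is
feasible only for tiny n1 (the brute-force oracle); for realistic sizes a
Metropolis chain over balanced allocations is used, with a proposal that
swaps the labels of one treated and one untreated subject (so every state is
balanced) and an acceptance ratio involving only the two swapped subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .model import conditional_error_unblinded, log_likelihood_ratio, z_statistic
from .params import EndpointParams, ReassessmentDecision, Stage1Data

__all__ = [
    "AllocationSample",
    "exact_allocation_posterior",
    "mcmc_sample_allocations",
    "conditional_error_mcmc",
    "maximize_conditional_error_mcmc",
]

_MAX_ENUM_N1 = 14


@dataclass(frozen=True)
class AllocationSample:
    """Retained draws from the posterior over balanced allocations."""

    draws: np.ndarray  # (n_draws, n1) 0/1, each row sums to n1/2
    weights: Optional[np.ndarray] = None  # uniform when None (pure MCMC)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def exact_allocation_posterior(data: Stage1Data, params: EndpointParams):
    """Full posterior over balanced allocations by enumeration (n1 <= 14).

    Returns ``(allocations, probabilities)`` with allocations of shape
    (C(n1, n1/2), n1).  Probability of a sequence is proportional to the
    product of per-subject densities; since the arms share the covariance,
    only the per-subject log likelihood ratios enter.
    """
    n1 = data.n1
    if n1 % 2:
        raise ValueError("n1 must be even")
    if n1 > _MAX_ENUM_N1:
        raise ValueError(f"enumeration limited to n1 <= {_MAX_ENUM_N1}, got {n1}")
    llr = np.asarray(log_likelihood_ratio(data.x, data.y, params), dtype=float)
    idx = list(combinations(range(n1), n1 // 2))
    allocs = np.zeros((len(idx), n1), dtype=np.int64)
    for k, treated in enumerate(idx):
        allocs[k, list(treated)] = 1
    logs = allocs @ np.where(np.isfinite(llr), llr, np.sign(llr) * 1e300)
    logs = logs - logs.max()
    p = np.exp(np.maximum(logs, -745.0))
    p /= p.sum()
    return allocs, p


def mcmc_sample_allocations(
    data: Stage1Data,
    params: EndpointParams,
    n_iter: int = 2000,
    burn_in: int = 1000,
    thin: Optional[int] = None,
    seed: int = 0,
) -> AllocationSample:
    """Metropolis sampler over balanced allocations.

    Proposal: pick one treated and one untreated subject uniformly and swap
    their labels.  The log acceptance ratio is llr(new treated) - llr(old
    treated), involving only the two subjects.  ``burn_in`` counts sweeps of
    n1 proposals; ``thin`` is the number of proposals between retained draws
    (default n1).  ``n_iter`` retained draws are returned, reproducibly for a
    given seed.
    """
    if n_iter <= 0 or burn_in < 0:
        raise ValueError("n_iter must be > 0 and burn_in >= 0")
    n1 = data.n1
    if n1 % 2:
        raise ValueError("n1 must be even")
    if thin is None:
        thin = n1
    if thin <= 0:
        raise ValueError("thin must be > 0")
    rng = np.random.default_rng(seed)
    llr = np.asarray(log_likelihood_ratio(data.x, data.y, params), dtype=float)
    llr = np.where(np.isfinite(llr), llr, np.sign(llr) * 1e300)

    half = n1 // 2
    perm = rng.permutation(n1)
    treated = list(perm[:half])
    control = list(perm[half:])

    total = burn_in * n1 + n_iter * thin
    pick_t = rng.integers(0, half, size=total)
    pick_c = rng.integers(0, half, size=total)
    logu = np.log(rng.random(size=total))

    draws = np.zeros((n_iter, n1), dtype=np.int64)
    kept = 0
    next_keep = burn_in * n1 + thin - 1
    for it in range(total):
        i, j = pick_t[it], pick_c[it]
        delta = llr[control[j]] - llr[treated[i]]
        if delta >= 0 or logu[it] < delta:
            treated[i], control[j] = control[j], treated[i]
        if it == next_keep:
            draws[kept, treated] = 1
            kept += 1
            next_keep += thin
    return AllocationSample(draws=draws[:kept])


def conditional_error_mcmc(
    data: Stage1Data,
    params: EndpointParams,
    n2: float,
    alpha: float,
    sample: AllocationSample,
) -> float:
    """Blinded conditional error as a posterior average over allocations.

    Averages the unblinded conditional error at Z1(g) over the sampled
    allocations g (weighted if the sample carries weights).
    """
    if sample.n_draws == 0:
        raise ValueError("empty allocation sample")
    signs = 2.0 * sample.draws - 1.0
    z1 = signs @ data.x / (params.sigma * np.sqrt(data.n1))
    ce = conditional_error_unblinded(z1, data.n1, n2, alpha)
    ce = np.atleast_1d(ce)
    if sample.weights is not None:
        w = np.asarray(sample.weights, dtype=float)
        return float(np.sum(w * ce) / np.sum(w))
    return float(np.mean(ce))


def maximize_conditional_error_mcmc(
    data: Stage1Data,
    params: EndpointParams,
    design,
    alpha: float,
    sample: AllocationSample,
    n2_grid,
) -> ReassessmentDecision:
    """Grid argmax of the MCMC conditional error over candidate n2 values.

    Ties are broken toward the smallest n2.
    """
    grid = np.asarray(list(n2_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty n2 grid")
    order = np.argsort(grid)
    grid = grid[order]
    ces = np.array(
        [conditional_error_mcmc(data, params, n2, alpha, sample) for n2 in grid]
    )
    k = int(np.argmax(ces))
    return ReassessmentDecision(n2=float(grid[k]), conditional_error=float(ces[k]))


def default_n2_grid(design, n_points: int = 200) -> np.ndarray:
    """Geometric candidate grid over [max(n2min, 1), n2max] plus endpoints.

    When n2max is unbounded the grid tops out at 100*n1 and the unbounded
    sentinel is appended (its conditional error is the limit alpha).
    """
    lo = max(design.n2min, 1.0)
    hi = design.n2max if np.isfinite(design.n2max) else 100.0 * design.n1
    grid = np.geomspace(lo, hi, n_points)
    extra = [design.n2min]
    if not np.isfinite(design.n2max):
        extra.append(np.inf)
    return np.unique(np.concatenate([grid, np.asarray(extra, dtype=float)]))
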