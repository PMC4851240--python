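"""Seeded generators for trial data under each randomization scheme.

Responses follow the bivariate normal model: given the allocation G_i = g,

    (X_i, Y_i) ~ N( (mu_g, nu_g), sigma^2 [[1, rho], [rho, 1]] ).

Allocation schemes: ``simple`` (iid fair coin), ``random_allocation``
(uniform over the exactly balanced assignments) and ``block`` (independent
uniform balanced sequence per consecutive block of length tau).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .params import EndpointParams, Stage1Data, TrialDesign

__all__ = ["simulate_stage1", "simulate_stage2"]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _balanced(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draw from the C(n, n/2) balanced 0/1 vectors of length n."""
    g = np.zeros(n, dtype=np.int64)
    g[rng.permutation(n)[: n // 2]] = 1
    return g


def _responses(rng, g, params: EndpointParams):
    """Draw (x, y) given allocations; exact for |rho| = 1."""
    g = np.asarray(g)
    z1 = rng.standard_normal(g.shape)
    z2 = rng.standard_normal(g.shape)
    mu = np.where(g == 1, params.mu1, params.mu0)
    nu = np.where(g == 1, params.nu1, params.nu0)
    r = params.rho
    x = mu + params.sigma * z1
    y = nu + params.sigma * (r * z1 + np.sqrt(max(1.0 - r * r, 0.0)) * z2)
    return x, y


def simulate_stage1(
    params: EndpointParams, design: TrialDesign, seed: SeedLike = None
) -> Stage1Data:
    """One stage-1 dataset with the true allocation attached.

    The allocation is drawn according to ``design.scheme``; with the block
    scheme, ``block_id`` labels the consecutive blocks of length tau.
    """
    rng = _rng(seed)
    n1 = design.n1
    block_id: Optional[np.ndarray] = None
    if design.scheme == "simple":
        g = rng.integers(0, 2, size=n1)
    elif design.scheme == "random_allocation":
        g = _balanced(rng, n1)
    else:  # block
        tau = design.tau
        g = np.concatenate([_balanced(rng, tau) for _ in range(n1 // tau)])
        block_id = np.repeat(np.arange(n1 // tau), tau)
    x, y = _responses(rng, g, params)
    return Stage1Data(x=x, y=y, g=g, block_id=block_id)


def simulate_stage2(params: EndpointParams, n2: int, seed: SeedLike = None):
    """One balanced second-stage dataset; returns ``(x, y, g)``.

    Only x feeds the final test statistic, but y is generated for
    completeness (same response model as stage 1).
    """
    if n2 % 2 or n2 < 2:
        raise ValueError(f"n2 must be even and >= 2, got {n2}")
    rng = _rng(seed)
    g = _balanced(rng, n2)
    x, y = _responses(rng, g, params)
    return x, y, g
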