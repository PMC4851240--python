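"""Domain types for the blinded sample-size-reassessment model.

The trial under study is a two-arm parallel-group superiority comparison with
a normally distributed primary endpoint X and a secondary endpoint Y that is
bivariate normal with X given the treatment indicator G.  Both endpoints share
a common standard deviation ``sigma`` and correlation ``rho``; only the means
differ between arms.  A blinded interim analysis after ``n1`` subjects may
choose the second-stage sample size ``n2`` within ``[n2min, n2max]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Sentinel for an unbounded second-stage sample size.
UNBOUNDED = math.inf

SCHEMES = ("simple", "random_allocation", "block")


@dataclass(frozen=True)
class EndpointParams:
    """Means and joint dispersion of the (primary, secondary) endpoint pair.

    Parameters
    ----------
    mu0, mu1 : float
        Primary-endpoint means under control / treatment (response units).
    nu0, nu1 : float
        Secondary-endpoint means under control / treatment.
    sigma : float
        Common standard deviation of both endpoints, > 0.
    rho : float
        Correlation between the endpoints, in [-1, 1].  |rho| = 1 is the
        degenerate fully-informative case and is handled exactly.
    """

    mu0: float
    mu1: float
    nu0: float
    nu1: float
    sigma: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")

    @property
    def secondary_effect(self) -> float:
        """Treatment effect in the secondary endpoint, nu1 - nu0."""
        return self.nu1 - self.nu0

    def mean(self, g: int) -> tuple[float, float]:
        """Mean vector of (X, Y) for arm ``g`` (0 control, 1 treatment)."""
        return (self.mu1, self.nu1) if g else (self.mu0, self.nu0)


@dataclass(frozen=True)
class TrialDesign:
    """First-stage size, second-stage bounds, level and randomization scheme.

    ``n2max`` may be :data:`UNBOUNDED` (``math.inf``); the reassessment rule
    then treats the second stage as unrestricted and the attained conditional
    error of an unbounded choice is its limit value ``alpha``.
    """

    n1: int
    n2min: float = 0.0
    n2max: float = UNBOUNDED
    alpha: float = 0.025
    scheme: str = "random_allocation"
    tau: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n1 % 2:
            raise ValueError(f"n1 must be a positive even integer, got {self.n1}")
        if self.n2min < 0:
            raise ValueError(f"n2min must be >= 0, got {self.n2min}")
        if not self.n2min < self.n2max:
            raise ValueError(f"need n2min < n2max, got [{self.n2min}, {self.n2max}]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.scheme == "block":
            if self.tau is None:
                raise ValueError("block scheme requires tau")
            if self.tau % 2 or self.tau <= 0:
                raise ValueError(f"tau must be a positive even integer, got {self.tau}")
            if self.n1 % self.tau:
                raise ValueError(f"tau={self.tau} must divide n1={self.n1}")


@dataclass
class Stage1Data:
    """Blinded first-stage responses, optionally with the true allocation.

    ``x`` and ``y`` are the primary/secondary responses of the ``n1`` interim
    subjects.  ``g`` (0/1 allocation indicators) and ``block_id`` are only
    available to the simulator / validator, never to the blinded rule.
    """

    x: np.ndarray
    y: np.ndarray
    g: Optional[np.ndarray] = None
    block_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if self.g is not None:
            self.g = np.asarray(self.g)
            if self.g.shape != self.x.shape:
                raise ValueError("g must match x in length")
            if not np.isin(self.g, (0, 1)).all():
                raise ValueError("g must contain only 0/1")
        if self.block_id is not None:
            self.block_id = np.asarray(self.block_id)
            if self.block_id.shape != self.x.shape:
                raise ValueError("block_id must match x in length")

    @property
    def n1(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class ConditionalLaw:
    """Normal approximation to the law of Z1 given the blinded stage-1 data.

    ``mean`` and ``variance`` are m1/V1 for unblocked designs or mZ1/vZ1 when
    block information is used.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")


@dataclass(frozen=True)
class ReassessmentDecision:
    """A chosen second-stage size and the conditional error it attains."""

    n2: float
    conditional_error: float


@dataclass(frozen=True)
class SimulationConfig:
    """A complete Monte Carlo study configuration."""

    params: EndpointParams
    design: TrialDesign
    n_runs: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
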