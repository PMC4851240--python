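"""Block-randomization machinery: sequence enumeration and block posteriors.

With balanced blocks of even length tau there are K = C(tau, tau/2) admissible
allocation sequences per block, each with prior 1/K.  Given the blinded data
b_i of a block, the posterior of sequence omega_k is proportional to the
product of the per-subject bivariate normal densities under that sequence.
Per-block posterior means and variances of the block score

    m_{tau,i}(k) = sum_l (2 omega_{k,l} - 1) x_{i+l}

aggregate (blocks are independent given the data) into the conditional mean
mZ1 and variance vZ1 of the stage-1 z-statistic, which feed the same
worst-case reassessment rule as the unblocked case.

Convention: omega = 1 means treatment (group B), omega = 0 control (group A);
flipping the convention negates mZ1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .model import _worst_case_arrays, log_likelihood_ratio
from .params import ConditionalLaw, EndpointParams, ReassessmentDecision, Stage1Data, TrialDesign

__all__ = [
    "BlockAllocationSet",
    "BlockPosterior",
    "enumerate_block_allocations",
    "block_posterior",
    "block_conditional_moments",
    "worst_case_n2_block",
]

_MAX_TAU = 12


@dataclass(frozen=True)
class BlockAllocationSet:
    """All balanced 0/1 allocation sequences of one block."""

    tau: int
    sequences: np.ndarray  # (K, tau) int array, each row sums to tau/2

    @property
    def K(self) -> int:
        return self.sequences.shape[0]


@dataclass(frozen=True)
class BlockPosterior:
    """Posterior over the K sequences of one block, with block scores."""

    probabilities: np.ndarray  # (K,), nonnegative, sums to 1
    block_scores: np.ndarray  # (K,), m_{tau,i}(k)


def enumerate_block_allocations(tau: int) -> BlockAllocationSet:
    """All C(tau, tau/2) balanced sequences of length tau, lexicographic."""
    if tau % 2 or tau < 2 or tau > _MAX_TAU:
        raise ValueError(f"tau must be even with 2 <= tau <= {_MAX_TAU}, got {tau}")
    seqs = np.zeros((comb(tau, tau // 2), tau), dtype=np.int64)
    for k, treated in enumerate(combinations(range(tau), tau // 2)):
        seqs[k, list(treated)] = 1
    return BlockAllocationSet(tau=tau, sequences=seqs)


def _arm_log_densities(x, y, params: EndpointParams):
    """(log f(.|control), log f(.|treatment)) per subject; |rho|=1 handled.

    In the degenerate case each arm's density concentrates on a line; the log
    density is 0 for the arm whose line the observation is (numerically)
    nearest to and -inf for the other (both 0 on ties), which is the exact
    limit up to a constant that cancels in normalization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if abs(params.rho) == 1.0:
        sgn = 1.0 if params.rho > 0 else -1.0
        r1 = np.abs((y - params.nu1) - sgn * (x - params.mu1))
        r0 = np.abs((y - params.nu0) - sgn * (x - params.mu0))
        l0 = np.where(r0 <= r1, 0.0, -np.inf)
        l1 = np.where(r1 <= r0, 0.0, -np.inf)
        return l0, l1
    s, r = params.sigma, params.rho
    det = 1.0 - r * r

    def logpdf(mx, my):
        a = (x - mx) / s
        b = (y - my) / s
        quad = (a * a - 2 * r * a * b + b * b) / det
        return -0.5 * quad - np.log(2 * np.pi * s * s * np.sqrt(det))

    return logpdf(params.mu0, params.nu0), logpdf(params.mu1, params.nu1)


def block_posterior(
    block_x, block_y, params: EndpointParams, allocs: BlockAllocationSet
) -> BlockPosterior:
    """Posterior P(omega_k | b_i) and scores m_{tau,i}(k) for one block."""
    x = np.asarray(block_x, dtype=float)
    y = np.asarray(block_y, dtype=float)
    if x.size != allocs.tau or y.size != allocs.tau:
        raise ValueError(f"block must have exactly tau={allocs.tau} subjects")
    l0, l1 = _arm_log_densities(x, y, params)
    w = allocs.sequences  # (K, tau)
    # sum_l log f(x_l, y_l | arm w_{k,l}) via indexing (inf-safe)
    logs = np.where(w == 1, l1[None, :], l0[None, :]).sum(axis=1)
    m = np.max(logs)
    if not np.isfinite(m):
        raise ValueError("all allocation sequences have zero likelihood")
    p = np.exp(logs - m)
    p /= p.sum()
    scores = (2 * w - 1) @ x
    return BlockPosterior(probabilities=p, block_scores=scores)


def block_conditional_moments(
    data: Stage1Data, tau: int, params: EndpointParams
) -> ConditionalLaw:
    """Conditional mean mZ1 and variance vZ1 of Z1 given blinded blocked data.

    Blocks are the consecutive index ranges {0..tau-1}, {tau..2tau-1}, ...;
    they contribute independently:

        mZ1 = sum_blocks E[m_tau | b] / (sigma sqrt(n1)),
        vZ1 = sum_blocks Var[m_tau | b] / (sigma^2 n1).
    """
    n1 = data.n1
    if n1 % tau:
        raise ValueError(f"tau={tau} must divide n1={n1}")
    allocs = enumerate_block_allocations(tau)
    mean_sum = 0.0
    var_sum = 0.0
    for start in range(0, n1, tau):
        post = block_posterior(
            data.x[start : start + tau], data.y[start : start + tau], params, allocs
        )
        e1 = float(post.probabilities @ post.block_scores)
        e2 = float(post.probabilities @ post.block_scores**2)
        mean_sum += e1
        var_sum += max(e2 - e1 * e1, 0.0)
    s = params.sigma
    return ConditionalLaw(
        mean=mean_sum / (s * np.sqrt(n1)), variance=var_sum / (s * s * n1)
    )


def worst_case_n2_block(
    data: Stage1Data, tau: int, params: EndpointParams, design: TrialDesign
) -> ReassessmentDecision:
    """Worst-case second-stage size using block information (mZ1, vZ1).

    Identical to the unblocked closed-form rule with (m1, V1) replaced by the
    block-informed conditional moments.
    """
    law = block_conditional_moments(data, tau, params)
    n2, ce = _worst_case_arrays(
        law.mean, law.variance, design.n1, design.n2min, design.n2max, design.alpha
    )
    return ReassessmentDecision(n2=float(n2), conditional_error=float(ce))


def block_marginal_treatment_probs(
    data: Stage1Data, tau: int, params: EndpointParams
) -> np.ndarray:
    """Per-subject marginal posterior treatment probabilities under blocking.

    sum_k P(omega_k | b_i) * omega_{k,j} for each subject j of each block.
    For tau = 2 this reduces to the two-hypothesis Bayes computation.
    """
    n1 = data.n1
    if n1 % tau:
        raise ValueError(f"tau={tau} must divide n1={n1}")
    allocs = enumerate_block_allocations(tau)
    out = np.empty(n1)
    for start in range(0, n1, tau):
        post = block_posterior(
            data.x[start : start + tau], data.y[start : start + tau], params, allocs
        )
        out[start : start + tau] = post.probabilities @ allocs.sequences
    return out


def block_llr_scores(x_blocks, y_blocks, params: EndpointParams, allocs: BlockAllocationSet):
    """Vectorized per-sequence posteriors for many blocks at once (|rho| < 1).

    ``x_blocks``/``y_blocks`` have shape (..., tau).  Because the two arms
    share the covariance, log f(b|omega) differs from a baseline only by
    sum_l omega_l * llr_l, so posteriors are a softmax of W @ llr.  Returns
    (probabilities, scores) of shape (..., K).
    """
    if abs(params.rho) == 1.0:
        raise ValueError("vectorized path requires |rho| < 1")
    llr = log_likelihood_ratio(x_blocks, y_blocks, params)
    w = allocs.sequences.astype(float)  # (K, tau)
    s = llr @ w.T  # (..., K)
    s -= s.max(axis=-1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=-1, keepdims=True)
    scores = np.asarray(x_blocks, dtype=float) @ (2 * w - 1).T
    return p, scores
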