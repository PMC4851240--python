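"""Block randomization: enumeration, posteriors, conditional moments."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from blindsr import (
    EndpointParams,
    Stage1Data,
    TrialDesign,
    block_conditional_moments,
    block_posterior,
    enumerate_block_allocations,
    worst_case_n2,
    worst_case_n2_block,
    z_statistic,
)
from blindsr.blocks import block_llr_scores, block_marginal_treatment_probs
from blindsr.model import conditional_moments
from blindsr.params import ConditionalLaw


def _density(x, y, g, params):
    """Independent bivariate-normal density oracle (scipy)."""
    mean = (params.mu1, params.nu1) if g else (params.mu0, params.nu0)
    cov = params.sigma**2 * np.array([[1.0, params.rho], [params.rho, 1.0]])
    return multivariate_normal(mean=mean, cov=cov).pdf([x, y])


class TestEnumeration:
    @pytest.mark.parametrize("tau,expected", [(2, 2), (4, 6), (6, 20)])
    def test_counts(self, tau, expected):
        assert enumerate_block_allocations(tau).K == expected

    def test_tau4_matches_listed_set(self):
        seqs = {tuple(s) for s in enumerate_block_allocations(4).sequences}
        # A = control (0), B = treatment (1): AABB, ABAB, ABBA, BABA, BBAA, BAAB
        expected = {
            (0, 0, 1, 1), (0, 1, 0, 1), (0, 1, 1, 0),
            (1, 0, 1, 0), (1, 1, 0, 0), (1, 0, 0, 1),
        }
        assert seqs == expected

    def test_each_sequence_balanced_and_distinct(self):
        allocs = enumerate_block_allocations(6)
        assert (allocs.sequences.sum(axis=1) == 3).all()
        assert len({tuple(s) for s in allocs.sequences}) == allocs.K

    def test_deterministic_order(self):
        a = enumerate_block_allocations(4).sequences
        b = enumerate_block_allocations(4).sequences
        assert (a == b).all()

    @pytest.mark.parametrize("tau", [3, 0, 14])
    def test_invalid_tau(self, tau):
        with pytest.raises(ValueError):
            enumerate_block_allocations(tau)


class TestBlockPosterior:
    def test_identical_arms_uniform(self, uninformative_params, rng):
        allocs = enumerate_block_allocations(4)
        post = block_posterior(rng.normal(size=4), rng.normal(size=4),
                               uninformative_params, allocs)
        assert post.probabilities == pytest.approx(np.full(6, 1 / 6))

    def test_normalization(self, informative_params, rng):
        allocs = enumerate_block_allocations(6)
        for _ in range(5):
            post = block_posterior(rng.normal(size=6), rng.normal(size=6),
                                   informative_params, allocs)
            assert post.probabilities.sum() == pytest.approx(1.0)
            assert (post.probabilities >= 0).all()

    def test_tau2_two_hypothesis_bayes(self, informative_params):
        """Block of two: posterior equals the direct AB-vs-BA computation."""
        x = np.array([0.4, -0.2])
        y = np.array([0.0, 2.0])
        allocs = enumerate_block_allocations(2)
        post = block_posterior(x, y, informative_params, allocs)
        p = informative_params
        like = {
            tuple(seq): _density(x[0], y[0], seq[0], p) * _density(x[1], y[1], seq[1], p)
            for seq in allocs.sequences
        }
        total = sum(like.values())
        for k, seq in enumerate(allocs.sequences):
            assert post.probabilities[k] == pytest.approx(like[tuple(seq)] / total)
        # the second subject (y=2) is overwhelmingly the treated one
        k_ba = [tuple(s) for s in allocs.sequences].index((0, 1))
        assert post.probabilities[k_ba] == pytest.approx(1 / (1 + np.exp(-4.0)))

    def test_scores_match_sign_convention(self, informative_params):
        x = np.array([1.0, 2.0])
        allocs = enumerate_block_allocations(2)
        post = block_posterior(x, np.zeros(2), informative_params, allocs)
        for k, seq in enumerate(allocs.sequences):
            assert post.block_scores[k] == pytest.approx(np.sum((2 * seq - 1) * x))

    def test_wrong_block_length(self, informative_params):
        allocs = enumerate_block_allocations(4)
        with pytest.raises(ValueError):
            block_posterior(np.zeros(3), np.zeros(3), informative_params, allocs)


class TestBlockConditionalMoments:
    def test_identical_arms_zero_mean(self, uninformative_params, rng):
        data = Stage1Data(x=rng.normal(size=8), y=rng.normal(size=8))
        law = block_conditional_moments(data, 4, uninformative_params)
        assert law.mean == pytest.approx(0.0, abs=1e-12)

    def test_single_block_matches_enumeration(self, informative_params, rng):
        """tau = n1 = 4: exhaustive expectation over the 6 sequences."""
        x = rng.normal(size=4)
        y = rng.normal(size=4) + np.array([0, 2, 0, 2])
        data = Stage1Data(x=x, y=y)
        law = block_conditional_moments(data, 4, informative_params)
        p = informative_params
        allocs = enumerate_block_allocations(4)
        like = np.array(
            [np.prod([_density(x[l], y[l], seq[l], p) for l in range(4)])
             for seq in allocs.sequences]
        )
        probs = like / like.sum()
        scores = allocs.sequences @ x * 2 - x.sum()
        mean = probs @ scores / (p.sigma * 2.0)
        var = (probs @ scores**2 - (probs @ scores) ** 2) / (p.sigma**2 * 4.0)
        assert law.mean == pytest.approx(mean)
        assert law.variance == pytest.approx(var)

    def test_full_unblinding_limit(self, rng):
        p = EndpointParams(mu0=0.0, mu1=0.0, nu0=0.0, nu1=50.0, sigma=1.0, rho=0.0)
        n1, tau = 8, 2
        g = np.tile([1, 0], n1 // tau)
        x = rng.normal(size=n1)
        y = np.where(g == 1, p.nu1, p.nu0) + rng.normal(size=n1)
        data = Stage1Data(x=x, y=y)
        law = block_conditional_moments(data, tau, p)
        assert law.variance == pytest.approx(0.0, abs=1e-8)
        assert law.mean == pytest.approx(z_statistic(x, g, 1.0), abs=1e-6)

    def test_swapping_arms_negates_mean(self, informative_params, rng):
        data = Stage1Data(x=rng.normal(size=8), y=rng.normal(size=8))
        p = informative_params
        swapped = EndpointParams(mu0=p.mu1, mu1=p.mu0, nu0=p.nu1, nu1=p.nu0,
                                 sigma=p.sigma, rho=p.rho)
        a = block_conditional_moments(data, 4, p)
        b = block_conditional_moments(data, 4, swapped)
        assert b.mean == pytest.approx(-a.mean)
        assert b.variance == pytest.approx(a.variance)

    def test_partial_blocks_rejected(self, informative_params):
        data = Stage1Data(x=np.zeros(6), y=np.zeros(6))
        with pytest.raises(ValueError):
            block_conditional_moments(data, 4, informative_params)

    def test_blocking_adds_information(self, informative_params, rng):
        """Average conditional variance with tau=2 is below the unblocked one."""
        from blindsr.model import allocation_posterior

        n1, reps = 16, 300
        diffs = []
        for _ in range(reps):
            g = np.concatenate([rng.permutation([0, 1]) for _ in range(n1 // 2)])
            x = rng.normal(size=n1)
            y = np.where(g == 1, 2.0, 0.0) + rng.normal(size=n1)
            data = Stage1Data(x=x, y=y)
            blocked = block_conditional_moments(data, 2, informative_params)
            q = allocation_posterior(x, y, informative_params)
            unblocked = conditional_moments(data, q, 1.0)
            diffs.append(unblocked.variance - blocked.variance)
        assert np.mean(diffs) > 0

    def test_monotone_unblinding(self, rng):
        """Mean conditional variance shrinks as the secondary effect grows."""
        n1, tau, reps = 12, 4, 200
        means = []
        for effect in (0.5, 2.0, 4.0):
            p = EndpointParams(0.0, 0.0, 0.0, effect, 1.0, 0.0)
            vs = []
            for _ in range(reps):
                g = np.concatenate(
                    [rng.permutation([0, 0, 1, 1]) for _ in range(n1 // tau)]
                )
                x = rng.normal(size=n1)
                y = np.where(g == 1, effect, 0.0) + rng.normal(size=n1)
                vs.append(block_conditional_moments(Stage1Data(x=x, y=y), tau, p).variance)
            means.append(np.mean(vs))
        assert means[0] > means[1] > means[2]


class TestVectorizedPath:
    def test_fast_path_matches_block_posterior(self, rng):
        p = EndpointParams(0.0, 0.0, 0.0, 1.2, 1.3, 0.5)
        allocs = enumerate_block_allocations(4)
        xb = rng.normal(size=(7, 3, 4))
        yb = rng.normal(size=(7, 3, 4))
        probs, scores = block_llr_scores(xb, yb, p, allocs)
        for i in (0, 3, 6):
            for j in range(3):
                post = block_posterior(xb[i, j], yb[i, j], p, allocs)
                assert probs[i, j] == pytest.approx(post.probabilities)
                assert scores[i, j] == pytest.approx(post.block_scores)

    def test_fast_path_rejects_degenerate_rho(self):
        p = EndpointParams(0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            block_llr_scores(np.zeros((1, 2)), np.zeros((1, 2)), p,
                             enumerate_block_allocations(2))


class TestBlockMarginals:
    def test_in_unit_interval_and_balanced_on_average(self, informative_params, rng):
        n1 = 400
        g = np.concatenate([rng.permutation([0, 0, 1, 1]) for _ in range(n1 // 4)])
        x = rng.normal(size=n1)
        y = np.where(g == 1, 2.0, 0.0) + rng.normal(size=n1)
        m = block_marginal_treatment_probs(Stage1Data(x=x, y=y), 4, informative_params)
        assert ((m >= 0) & (m <= 1)).all()
        assert m.mean() == pytest.approx(0.5, abs=0.05)

    def test_tau2_equals_two_hypothesis_bayes(self, informative_params, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        m = block_marginal_treatment_probs(Stage1Data(x=x, y=y), 2, informative_params)
        p = informative_params
        for b in range(3):
            i, j = 2 * b, 2 * b + 1
            ab = _density(x[i], y[i], 0, p) * _density(x[j], y[j], 1, p)
            ba = _density(x[i], y[i], 1, p) * _density(x[j], y[j], 0, p)
            assert m[i] == pytest.approx(ba / (ab + ba))
            assert m[j] == pytest.approx(ab / (ab + ba))


class TestWorstCaseBlock:
    def test_matches_grid_oracle(self, rng, grid_oracle, informative_params):
        design = TrialDesign(n1=8, n2min=4, n2max=64, scheme="block", tau=4)
        for _ in range(10):
            g = np.concatenate([rng.permutation([0, 0, 1, 1]) for _ in range(2)])
            x = rng.normal(size=8)
            y = np.where(g == 1, 2.0, 0.0) + rng.normal(size=8)
            data = Stage1Data(x=x, y=y)
            dec = worst_case_n2_block(data, 4, informative_params, design)
            law = block_conditional_moments(data, 4, informative_params)
            oracle = grid_oracle(law.mean, law.variance, 8, 4, 64, design.alpha,
                                 n_points=2000)
            assert dec.conditional_error >= oracle - 1e-6

    def test_identical_arms_same_branch_as_unblocked(self, uninformative_params, rng):
        """With no secondary effect both rules see mean 0; when their variances
        fall on the same side of 1 the chosen bound coincides."""
        design = TrialDesign(n1=8, n2min=4, n2max=64, scheme="block", tau=2)
        data = Stage1Data(x=rng.normal(size=8), y=rng.normal(size=8))
        blocked = worst_case_n2_block(data, 2, uninformative_params, design)
        law = conditional_moments(data, np.full(8, 0.5), uninformative_params.sigma)
        unblocked = worst_case_n2(law, design)
        blocked_law = block_conditional_moments(data, 2, uninformative_params)
        assert blocked_law.mean == pytest.approx(0.0, abs=1e-12)
        if (law.variance - 1) * (blocked_law.variance - 1) > 0:
            assert blocked.n2 == unblocked.n2
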