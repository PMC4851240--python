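# Methods

## The model and the question

`blindsr` studies a two-arm parallel-group superiority trial with a normally
distributed primary endpoint X and a secondary endpoint Y, jointly bivariate
normal given the treatment indicator G ∈ {0, 1}:

    (X, Y) | G = g  ~  N( (μ_g, ν_g),  σ² [[1, ρ], [ρ, 1]] ),

with a common known standard deviation σ and correlation ρ. The final
analysis rejects H₀: μ₁ ≤ μ₀ when the pooled z-statistic
Z_N = (σ√N)⁻¹ Σ (2G_i − 1) X_i exceeds z₁₋α, N = n₁ + n₂.

After n₁ subjects a *blinded* interim look observes the responses (x, y)
without treatment labels and may choose n₂ ∈ [n₂min, n₂max]. If the
secondary endpoint has a treatment effect (ν₁ ≠ ν₀) the blinded data carry
information about the allocation, so an adversarial choice of n₂ can inflate
the type I error even though the look was blinded. The package computes the
worst attainable rejection probability — an upper bound on the inflation —
under three randomization schemes: simple (iid fair coin), random allocation
(exactly n₁/2 treated), and permuted blocks of even length τ.

## Conditional error and the worst-case rule

Given the unblinded stage-1 statistic Z₁, the conditional rejection
probability at second-stage size n₂ is

    CE(z₁, n₂) = 1 − Φ( √(N/n₂) z₁₋α − √(n₁/n₂) z₁ ).

Blinded, the law of Z₁ given the data is approximated by N(m₁, V₁) with

    m₁ = Σ (2qᵢ − 1) xᵢ / (σ√n₁),   V₁ = 4 Σ xᵢ² qᵢ(1 − qᵢ) / (σ² n₁),

where qᵢ = φ_ν₁(xᵢ, yᵢ) / (φ_ν₀ + φ_ν₁)(xᵢ, yᵢ) is the per-subject Bayes
posterior of treatment under simple randomization (asymptotically valid
under random allocation as well). The blinded conditional error is then

    CE(m₁, V₁, n₂) = 1 − Φ( (z₁₋α − u m₁) / √((1 − u²) + V₁ u²) ),
    u = √(n₁/N).

Maximizing over n₂ (equivalently over u ∈ (0, 1]) by differentiation: the
derivative of the Φ-argument in u is proportional to z₁₋α(1 − V₁)u − m₁, so
the maximizer is one of

* the lower bound n₂min,
* the upper bound n₂max (as n₂max → ∞ the conditional error tends to α),
* the interior stationary point u* = m₁ / (z₁₋α(1 − V₁)), i.e.
  **n₂\* = n₁ [ (z₁₋α(1 − V₁)/m₁)² − 1 ]**, which exists as a maximum only
  when V₁ < 1 and m₁ > 0, clamped to the bounds.

`worst_case_n2` evaluates this finite candidate set exactly — no grid
search. When V₁ > 1 the stationary point is a *minimum* of the conditional
error, so only the two endpoints compete; this follows from the calculus and
is confirmed by the grid-search oracle in the test suite (agreement to 1e-6
on hundreds of random instances, which also fixes the squared grouping of
the interior formula). Degenerate corners are resolved by their limits:
n₂ = 0 with V₁ = 0 is the threshold indicator 1{m₁ > z₁₋α} (0.5 on the
boundary), and an unbounded selection reports n₂ = inf with conditional
error exactly α.

n₂ is treated as continuous in the rule; only the full-trial simulators
round it (to the nearest even integer, clamped to the bounds).

## Block randomization

With blocks of length τ there are K = C(τ, τ/2) balanced allocation
sequences per block, prior 1/K each. The block posterior is proportional to
the product of per-subject bivariate densities under the sequence. Because
both arms share the covariance, the log-density of a block under sequence ω
differs from a baseline only by Σ_l ω_l · llr_l with llr the per-subject
log likelihood ratio, so posteriors are a softmax of W·llr (max-shifted
against under/overflow); the scalar API (`block_posterior`) instead sums
per-arm log densities directly, which also covers |ρ| = 1. Per-block
posterior means and variances of the score m_τ = Σ (2ω_l − 1) x_l aggregate
into the conditional moments (m_Z₁, v_Z₁) of Z₁ — blocks are independent
given the data — and the same closed-form rule applies. Blocks are fixed
consecutive index ranges; partial blocks are rejected rather than guessed.
Sequence indicator convention: ω = 1 is treatment; flipping the convention
negates m_Z₁ (asserted in tests). Whether stage 2 is itself blocked does not
enter the conditional-error formula; the full-trial simulators use balanced
stage-2 allocation.

## Exact and MCMC evaluation under random allocation

Under random allocation the posterior over the C(n₁, n₁/2) balanced
assignment vectors is proportional to the product of per-subject densities.
`exact_allocation_posterior` enumerates it for n₁ ≤ 14 (the brute-force
oracle). `mcmc_sample_allocations` runs a Metropolis chain whose proposal
swaps the labels of one treated and one untreated subject — every state is
balanced, and the acceptance ratio involves only the two swapped subjects'
likelihood ratios (O(1) per proposal, computed on the log scale). Defaults:
burn-in 1,000 sweeps of n₁ proposals, thinning of n₁ proposals per retained
draw, 2,000 retained draws; all overridable. Any balance-preserving proposal
targeting this posterior would do; the chain is validated against
enumeration at small n₁. `conditional_error_mcmc` averages CE(Z₁(g), n₂)
over the retained draws; maximization over n₂ uses a geometric grid
(default 200 points, ties to the smallest n₂) because the posterior average
need not be unimodal.

## Degenerate correlation

At |ρ| = 1 the bivariate density is singular: given g, y − sign(ρ)·x is
deterministic. The posterior is then the exact indicator of which arm's line
the observation lies nearest to (0.5 on ties), implemented without singular
density arithmetic. This makes ρ = 1 the full-unblinding limit: q ∈ {0, 1},
m₁ = Z₁, V₁ = 0.

## Monte Carlo drivers and their sizes

`estimate_max_type1_analytic` simulates stage-1 datasets under H₀, applies
the worst-case rule and averages the blinded conditional error; its mc_se is
the per-run standard deviation over √n_runs. `estimate_max_type1_montecarlo`
instead simulates the whole trial and scores rejections (binomial mc_se),
with either the known-σ z-test or a pooled-variance t-test with N − 2
degrees of freedom at the final analysis. The reassessment rule always uses
the known-σ closed form; there is no t-specific rule. Stage-2 data enter the
t-test through exact per-arm sufficient statistics (normal group mean,
chi-squared sum of squares), which vectorizes across runs with different
realized n₂; when the rule selects an unbounded n₂ the realized size is
capped at 100·n₁, where the conditional error is within 4·10⁻⁴ of its limit
α at n₁ ≥ 144.

Simulation is vectorized across runs in chunks of about 2·10⁶ subject
records; a master `SeedSequence` spawns one independent substream per chunk,
so every result is reproducible from (config, seed). Study sizes used by the
reproduction script: 200,000 runs for the n₁ = 144 ceiling; 50,000 runs per
correlation point for the case-study and unblinding-correlation grids (10
equispaced ρ values on [0, 0.9]). Monte Carlo standard errors at these sizes
are below 7·10⁻⁴ for α_max and below 3·10⁻³ for r. The test suite uses
smaller sizes with tolerances widened by three standard errors.

## Case-study presets

The Fingolimod-style presets place H₀ on the primary endpoint (μ₀ = μ₁ = 0,
without loss of generality since σ is known) and take the secondary endpoint
as lymphocyte count (ν₀ = 1.8, ν₁ = 0.55, σ = 0.31, all ×10⁹ cells/L) or
total white blood cell count (ν₀ = 6.5, ν₁ = 3.8, pooled σ = 1.57), with
n₁ = 400 and either an unrestricted second stage or n₂ ∈ [200, 1600]. The
model's single σ is shared by both endpoints; the count nature of a real
relapse-rate endpoint is outside the model. The unblinding correlation r is
the Pearson correlation, across simulated trials under H₀, between the
unblinded effect estimate X̄ = Σ 2(2Gᵢ − 1)Xᵢ/n₁ and its blinded
reconstruction with qᵢ in place of Gᵢ; with ν₁ = ν₀ and ρ = 0 the blinded
estimate is degenerate at 0 and r is reported as 0.

## What the generator does and does not emulate

`simulate_stage1`/`simulate_stage2` draw exactly from the stated model:
normal endpoints, common known variance, 1:1 allocation, complete follow-up.
Real trials add estimated variances, non-normal endpoints, dropout, unequal
variances and time trends — none of which are modeled, so passing tests
certify the procedure's properties under the model, not robustness beyond
it. The known-σ assumption itself produces a small inflation even with an
uninformative secondary endpoint (the rule exploits excess blinded
variance); with a final t-test that artifact turns into slight conservatism
at zero secondary effect. Both behaviors are asserted in the tests.

## Numerical choices and known limitations

* z-quantiles via the standard normal inverse CDF; no tabulated constants.
* The conditional-error denominator is computed as (1 − u²) + V₁u², which is
  nonnegative by construction; the only true zero (u = 1, V₁ = 0) takes the
  threshold-rule limit.
* Oracle-equivalence tolerance for the closed-form rule: 1e-6 absolute in
  conditional error.
* Enumeration guards: τ ≤ 12 per block, n₁ ≤ 14 for full enumeration.
* The normal approximation N(m₁, V₁) is adequate for n₁ ≈ 144 when the
  standardized secondary effect is ≤ 2 and ρ ≤ 0.8 (checked against MCMC to
  0.005). At much larger effects (the case-study presets reach |ν₁ − ν₀|/σ ≈ 4)
  the conditional law of Z₁ becomes discrete and the approximation slightly
  overstates the maximum at high ρ — by a few 10⁻³ in the unrestricted
  lymphocyte setting — while the realized full-trial rejection rate runs
  slightly below it. The analytic (approximation-based) estimate is what the
  case-study driver reports.
* Only 1:1 allocation, equal variances and a single interim look are
  supported. Estimating the secondary-endpoint distribution from blinded
  data (e.g. by EM mixture fitting) is out of scope: the distribution is
  assumed known, as when Phase II data inform a Phase III design.
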