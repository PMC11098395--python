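# Methods

## Model

The logistic-exponential distribution LED(ν, η) has survival function
S(x) = 1/(1 + Ψ(x)^η) with Ψ(x) = e^{νx} − 1, density
f(x) = νη e^{νx} Ψ^{η−1}/(1 + Ψ^η)² and hazard h = f/S.  ν > 0 is a
rate (per unit time): the median is ln 2 / ν for every η.  η > 0 is a
dimensionless shape: η = 1 gives the exponential law with constant
hazard ν; η > 1 gives h(0⁺) = 0 with an initially rising hazard; η < 1
gives h(0⁺) = ∞.  Together with the magnitude of ν this produces
constant, monotone, bathtub and upside-down-bathtub hazard regimes,
which is why the family is attractive for equipment-failure and
survival data.

All code evaluates powers of Ψ through one log-space kernel,
log Ψ = νx + log(1 − e^{−νx}) with the inner factor via `expm1`, so
densities, survival values and likelihood terms stay finite and
accurate from νx ≈ 1e−300 up to νx ≈ 700.  At x = 0 the distribution
functions take their limits exactly (F = 0, S = 1); the density and
hazard at 0 are defined by limits (0 for η > 1, ν for η = 1, +∞ for
η < 1).

## Censoring mechanism and simulator

An IAT-II PCS experiment on n units with removal plan R (Σ Rᵢ = n − m)
and thresholds T₁ < T₂ ends in one of three cases: an ordinary
progressive Type-II sample (m-th failure before T₁), an adaptive
sample (m-th failure in (T₁, T₂); removals executed only at failures
before T₁, the rest withdrawn at X_m), or a hard-stopped sample (test
truncated at T₂ after k₂ < m failures).  Failure counts relative to a
threshold use strict inequality; a time exactly equal to a threshold
counts as not before it (ties have probability zero under the
continuous model, and tied *recorded* values in rounded real data are
tolerated by the containers).  Every sample satisfies the accounting
identity E₂ + Σ executed removals + B = n, enforced at construction.

The simulator generates failures sequentially: with r units at risk
after the previous failure at x, the next failure X satisfies
S(X)/S(x) = U^{1/r} (the minimum of r i.i.d. residual lifetimes),
inverted through the quantile function.  Removals follow the adaptive
rule above; the draw that would land beyond T₂ terminates the test.
This construction is validated in the test suite against a literal
oracle that draws n i.i.d. latent lifetimes and executes the
withdrawal and stopping rules on them directly (chi-square agreement
of the joint law of case and failure counts on small designs).  Should
a removal plan ever exceed the surviving count — impossible for the
standard plans, reachable after adaptation corner cases — the
simulator removes all survivors and flags the sample
(`truncated_removal`).  A hard stop before the first failure yields a
valid empty case-III sample; it carries two-parameter information only
through the censoring term, so fitting rejects it and the Monte Carlo
engine counts it as a failed replicate.

The generator is also the package's synthetic-data source.  It
emulates exactly the idealized experiment: i.i.d. LED lifetimes,
faithful executions of the design, no measurement rounding, no
heterogeneity between units, no model misspecification.  Passing
tests therefore demonstrate correctness of the inferential machinery
under the assumed model, not robustness of the LED to real-world
violations; the rounded, tied RME values are the only non-synthetic
input exercised.

## Likelihood, score, information

Dropping the parameter-free combinatorial constant (it cancels from
every estimator, interval and posterior), the log-likelihood is

l = E₂ ln(νη) + Σᵢ[(η−1) ln Ψᵢ + νxᵢ − 2 ln(1+Ψᵢ^η)]
    − Σᵢ Rᵢ ln(1+Ψᵢ^η) − B ln(1+Ψ_{T*}^η),

where the single terminal term covers all three cases (B = 0 for the
plain progressive sample; the anchor T* is the last failure or the
hard stop).  The score and the full 2×2 Hessian are implemented in
closed form from this expression and verified against central finite
differences in all three cases (relative 1e−6 for the gradient, 1e−4
for the Hessian).  The observed information is the negated Hessian;
its inverse at the MLE estimates the sampling covariance.

## Maximum likelihood

Optimization runs on θ = (ln ν, ln η) — positivity without box
constraints — by damped Newton ascent with the analytic gradient and
Hessian: steps are capped at 5 in max-norm on the log scale,
non-ascent directions fall back to the gradient, and a halving line
search guarantees monotone progress.  Starting points come from a
small heuristic grid (ν matched to the sample median at η = 1, η
perturbed a factor e either way, plus a mean-based rescaling); a
Nelder-Mead refinement and Newton polish follow if no start converges.
Convergence requires max|∂l/∂θ| < 1e−8·(1+|l|) and a positive-definite
observed information; anything else raises rather than returning a
bad point.

Intervals: estimate ± z_{ξ/2}·se for the parameters, and the delta
method for S(t), h(t) with exact gradients (∂S/∂ν = −ηΨ^{η−1}te^{νt}S²
etc., finite-difference-verified).  Following the convention of the
benchmark tables used for validation, intervals are *not* truncated to
natural ranges by default — an S(t) upper bound may exceed 1 — and a
`truncate` flag is available when the natural ranges are wanted.

## Bayesian inference

Independent gamma priors ν ~ G(a₁, b₁), η ~ G(a₂, b₂).  The sampler
is componentwise random-walk Metropolis-Hastings started at the MLE
with proposal standard deviations equal to the asymptotic standard
errors; each coordinate's acceptance ratio uses the **full joint
posterior**.  Single-coordinate "conditional" targets that drop
ν-dependent likelihood factors are sometimes quoted for this model;
they are not proper densities (the dropped factors diverge), so the
joint-posterior ratio — which reduces to the correct conditional in
each move — is the implementation.  Negative proposals are rejected
outright, equivalent to a posterior that vanishes off the support;
acceptance rates (recorded per coordinate) sit near 0.7 at the
packaged samples' scales.  The S(t) and h(t) chains are deterministic
transforms of the parameter chains.

Point estimates: posterior mean (squared-error loss) and the LINEX
estimator −(1/p) ln E[e^{−pθ}] evaluated by shifted log-sum-exp; the
LINEX estimate converges to the posterior mean as p → 0 and sits below
it for p > 0 (Jensen).  Credible intervals: equal-tailed percentile
intervals read from the order statistics of the post-burn-in draws
(the construction used by the reference analyses), plus a shortest-
window variant.  Correctness is anchored by a dense-grid 2-D
quadrature oracle on tiny complete samples.

Defaults: P = 10,000 iterations with Q = 1,000 burn-in for simulation
work; real-data analyses use P = 5,000 and the diffuse prior
a = b = 0.001 on both parameters.  For Monte Carlo arms the prior is
configurable and defaults to gamma priors centred at the generating
parameters with variance 0.5 (a mild shrinkage prior: a = 2μ², b = 2μ)
— a package choice, made once, for studying Bayes-vs-ML behaviour when
honest prior information exists.  Reported Bayes "standard errors" are
posterior standard deviations, labelled as such.

## Monte Carlo engine

Each replicate simulates a censored sample, fits the MLE, and (when
requested) runs the Bayes arms; replicates whose optimization fails
are dropped from all arms and counted.  Per-replicate seeds are
spawned from the master seed, so summaries are bit-reproducible.
"Average bias" is reported twice — the mean signed deviation and the
mean absolute deviation — because the term is used ambiguously in the
applied literature and the two differ by a factor of several for these
estimators; the MSE, average interval width and empirical coverage are
standard.  The Bayesian arms use a vectorized variant of the sampler
that advances all replicate chains in lock-step on padded arrays
(algorithmically identical to the scalar sampler and cross-checked
against it).

Problem sizes: the packaged study cell runs scheme I (all removals at
the first failure) with n = 40, m = 20, thresholds (0.4, 0.8) and
truth (ν, η) = (1.5, 1.2) at 2,000–4,000 replicates, with Bayes arms
at P = 1,500/Q = 300; these sizes give Monte Carlo standard errors
well below the effects being checked (e.g. ±0.005 on a coverage
probability at 2,000 replicates) while keeping the default suite
desk-scale.

## Goodness of fit

Complete-data fits are compared through the one-sample
Kolmogorov-Smirnov distance against the *fitted* CDF, with the
parameters-known null distribution for the p-value (exact for
n ≤ 100, asymptotic otherwise; both recorded).  Estimating the
parameters from the same data makes this p-value conservative (the
Lilliefors effect); the convention is kept deliberately because it is
the one the validation benchmarks use, and the caveat is attached to
the result object's documentation.  The Weibull alternative is fitted
by ML with fixed zero location via scipy.

## Design notes and limitations

* The packaged censored samples ship verbatim: the random choice of
  which survivors were withdrawn behind them is unrecorded, so they
  cannot be regenerated from the complete data and are treated as
  authoritative fixtures.  `censor_complete_data` makes that
  randomization explicit (uniform among survivors, seeded) for new
  analyses.
* The degenerate no-censoring design (m = n, R ≡ 0) is representable
  so complete data flow through the same interfaces.
* Benchmark reference tables for the real-data analyses list fitted
  pairs in (shape, rate) order; the package API always uses
  (ν = rate, η = shape), and only the acceptance script re-orders its
  reported components to match the reference layout.
* Known limitations: no expected (Fisher) information — only the
  observed matrix, whose expectation is analytically awkward here; no
  profile-likelihood or bootstrap-t intervals; hazard-shape inference
  near t = 0 for η < 1 is numerically delicate below t ≈ 1e−8; with
  very few observed failures (fewer than ~3) the fit legitimately
  refuses and downstream consumers must handle the failure count.
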