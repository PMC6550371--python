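# Methods

## Outcome model and conventions

A patient's outcome is the change in pain score from baseline at 26 weeks,
on a 100 mm visual analogue scale. Change = week-26 score − baseline score,
so negative change means improvement. Outcomes are modelled Gaussian with a
common variance 1/τ across arms; the model is deliberately pragmatic — it
neither adjusts for baseline scores nor truncates scores to [0, 100] (it
puts negligible mass outside ±100 mm for the beliefs of interest). μ_P is
the long-run average change on pamidronate, δ the difference adalimumab −
pamidronate (negative favours adalimumab), and μ_A = μ_P + δ.

## Conjugate opinion model

Belief about (μ_P, δ, τ) is Normal-Gamma: τ ~ Gamma(a₀, b₀) (shape/rate;
b₀ in mm²) and, given τ, (μ_P, δ) ~ N((μ_P0, δ₀), R/τ) with R a symmetric
positive-definite dimensionless 2×2 matrix. Integrating τ out,

* the marginal of cᵀ(μ_P, δ) is location-scale t with df = 2a₀, location
  cᵀ(μ_P0, δ₀), scale² = (b₀/a₀)·cᵀRc;
* the single-patient predictive on an arm adds the sampling variance:
  scale² = (b₀/a₀)·(1 + cᵀRc), with c = (1,0) for pamidronate and (1,1)
  for adalimumab.

These t laws are exact for this model and are used everywhere; no normal
approximation is made. (The published effect-direction probability 68.4% is
itself consistent only with t tails — a normal model gives ≈ 0.66.)
Credible intervals are equal-tailed throughout; the marginals are symmetric
t's, so equal-tailed and highest-density intervals coincide anyway.

## Elicitation and the fitted predictive

Experts answer, per arm, five questions "P(26-week score < t)" for a
strictly decreasing threshold ladder, anchored to a typical patient with a
60 mm baseline. The fitting rule is quantile regression: each stated
probability p is transformed to the standard-t quantile z(p) at the
predictive df, and the thresholds are regressed on z by ordinary least
squares. The intercept is the predictive location (score scale; the
baseline is subtracted to move to the change scale) and the slope the
scale. The rule is deterministic and closed-form, and exactly recovers any
answer set that already lies on a t CDF; on inconsistent answers it returns
the least-squares compromise. Probabilities of exactly 0% or 100% map to
infinite quantiles and are dropped from the fit (logged); at least two
interior answers are required. The fitting algorithm used in the original
exercise was not published; quantile regression was chosen here for its
determinism and exactness on self-consistent answers.

The question thresholds are configuration, not constants, because the
original questionnaire wording was not published. The shipped defaults
{60, 30, 20, 10, 5} mm are placeholders: priors fitted from the packaged
panel under these thresholds do **not** reproduce the published consensus
prior (the fitted pamidronate predictive median is about −25 mm against a
published mode of −32.3 mm) and are not presented as reproductions.

## Consensus and panel-to-belief assembly

Consensus is formed on the answer scale — the arithmetic mean of the
experts' probabilities per question (the aggregation the elicitation
meeting itself adopted; a median variant is available) — never by pooling
separately fitted distributions. Experts are weighted uniformly.

A full belief is assembled from the two per-arm predictive fits by a
variance decomposition: a common sampling variance s² (default: b₀/a₀ of
the calibrated consensus prior, ≈ 2.21 mm²) is split off each predictive
variance v², leaving parameter-uncertainty diagonals r = v²/s² − 1 for each
arm. With a between-arm opinion correlation ρ (default 0.99), the effect
variance is r_δδ = r_PP + r_AA − 2ρ√(r_PP r_AA) and R is assembled in
(μ_P, δ) coordinates with cov(μ_P, δ) = ρ√(r_PP r_AA) − r_PP. The high
default ρ encodes that experts' uncertainty about the two arms is mostly
shared, which is what makes the implied effect interval far narrower than
either arm's predictive spread. The decomposition rule and ρ are design
choices of this package (the original study did not publish its rule);
both are plainly logged by the pipeline.

## Calibration from published summaries

Elicitation studies publish summaries of the fitted prior, not its
hyperparameters. `calibrate_from_summaries` inverts the standard summary
set, one hyperparameter at a time:

* b₀ = v_q · G⁻¹(1−q; a₀, 1), where v_q is the published q-quantile of the
  outcome variance (default: 75th percentile 4.6 mm²) and G⁻¹ a unit-rate
  gamma quantile;
* μ_P0 and δ₀ from the published modes (t marginals are symmetric);
* r_δδ from the half-width of the published equal-tailed effect interval
  (default (−6.9, 11.5) mm at 90%);
* r_PP by matching the published predictive improvement probability on
  pamidronate (default 0.842).

a₀ is not identified by these summaries and is fixed at 2 (prior df 4),
the value jointly consistent with the published effect interval and
direction probability. R is diagonal: nothing published identifies the
off-diagonal, and all printed posterior intervals reproduce under the
diagonal choice. The "4.6 mm" variance percentile is read on the variance
scale (mm²), not as a standard deviation: only that reading reproduces the
printed posterior interval widths (a `variance_units="sd"` flag gives the
other reading). The calibration is idempotent — extracting the summaries
of its output and re-calibrating returns the same hyperparameters to
10⁻⁹ — and the published effect-direction probability is deliberately left
out of the construction as a held-out check: the calibrated prior gives
P(δ > 0) = 0.689 against the published 68.4%.

Reconstruction is exact only up to the rounding of the published summaries:
the nine printed posterior 90% interval endpoints under the three
hypothetical datasets reproduce to within 0.06 mm (most to 1 d.p.), with
two endpoints (the effect intervals of datasets 1 and 2) off by
0.05–0.06 mm.

## Conjugate update

With per-arm counts (n_P, n_A), means (x̄_P, x̄_A) and pooled variance s²
(denominator n_P + n_A − 2, the standard two-sample pooling), the design
cross-products for columns (intercept, adalimumab indicator) are formed and
the standard Normal-Gamma linear-model update applied: R_n⁻¹ = R⁻¹ + XᵀX,
θ_n = R_n(R⁻¹θ₀ + Xᵀy), a_n = a₀ + n/2, b_n = b₀ + ½(yᵀy + θ₀ᵀR⁻¹θ₀ −
θ_nᵀR_n⁻¹θ_n). All solves use symmetric positive-definite (Cholesky)
factorizations; b_n uses the residual form with R_n⁻¹ taken from the
factorization already at hand, avoiding catastrophic cancellation, and a
computed b_n ≤ 0 is raised as a numerical failure rather than clamped.
Updating with a summary is identical (to 10⁻⁹) to updating with any
individual-patient dataset sharing those sufficient statistics, and
sequential updates compose. Trials with fewer than 3 patients carry no
pooled variance; the update then treats within-arm residual scatter as
zero, which is exact when each arm has at most one patient.

## Decision rule and its evaluation

The trial declares a clinically relevant difference when the posterior
probability that either arm is beneficial on average (mean change < 0) and
better than the other by a relative margin exceeds a threshold (defaults:
margin 0.30, threshold 0.2). The margin is multiplicative — the winning
arm w beats arm l when μ_w ≤ (1 + margin)·μ_l — because the published
boundary scenario means satisfy μ_A = μ_P/1.3 exactly or nearly so (−40 →
−30.8, −26 → −20, −32.3 → −24.85 printed as −24.9). The two winning events
are disjoint for a positive margin (asserted on the draws); the rule
thresholds their union by default, with a max-of-the-two variant behind a
flag (the source is silent on which was used; under the null the two
differ negligibly).

The probability is evaluated by direct Monte Carlo from the closed-form
joint — draw τ, then (μ_P, δ) given τ — with 10,000 draws by default,
replacing the original study's external MCMC sampler; conjugacy makes the
joint exact, so sampler convergence is not a concern. Tests cross-check the
Monte Carlo against a closed-form bivariate-t half-plane oracle.

Operating characteristics: for each of 1000 simulated trials per scenario
(20 patients per arm; scenario truths taken verbatim from the published
scenario table), simulate Gaussian outcomes, update the prior with the
trial summary, evaluate the rule, and report the declared proportion with
its binomial standard error. Each trial consumes one substream spawned from
the master seed, so results are bit-for-bit reproducible and individual
trials replayable. The fraction of trials whose decision statistic fell
within 3 Monte-Carlo standard errors of the threshold is reported alongside
(`near_boundary_fraction`) as a handle on decisions the posterior Monte
Carlo could itself have flipped; at the default draw count it is under 1%
in the null scenarios. The full six-scenario study at the original sizes
(6 × 1000 trials × 10,000 draws) runs in a few seconds.

## Synthetic data generator

The panel generator emulates the structure the analysis assumes, not real
expert psychology. Each synthetic expert perturbs the true predictive's
location (additive Gaussian, sd = noise × scale) and log-scale (Gaussian,
sd = noise), answers with the perturbed CDF at the question thresholds,
rounds to a percent grid (default 5 — real panels answer predominantly in
multiples of 5), and clamps to [0, 100]. The perturbed CDF is monotone in
the threshold and rounding is a monotone map, so ladders can violate
monotonicity only by ties; a running-maximum sweep (the
pool-adjacent-violators solution for this already-ordered input, and one
that preserves the rounding grid) guards the invariant. Defaults — 13
experts, probit noise sd 0.1 — mirror the panel size of the original
exercise and a noise level at which 13-expert panels recover the true
predictive location to within ~3 mm on average. Patient-level data are
plain Gaussian draws per arm. All randomness descends from one master seed
through named substreams (experts, patients), so components are
independently reproducible. What passing recovery tests show is that the
pipeline inverts its own generative assumptions; they say nothing about
anchoring, overconfidence or other behaviour of real panels.

## Numerical and degenerate-input choices

* Singular R is rejected unless a belief is explicitly flagged degenerate;
  degenerate beliefs support marginals, predictives and Monte Carlo (via an
  eigen factor) but not updating.
* Zero-scale t distributions are point masses with step-function CDFs.
* A zero-width published effect interval, an improvement probability
  inconsistent with the sign of the mode, or a sampling variance not below
  both fitted predictive variances are all rejected with explicit errors
  rather than silently floored.
* Serialized beliefs round-trip losslessly (JSON repr floats); human-facing
  reports round to 1 decimal mm.

## Known limitations

* Two arms only; common variance only; no interim analyses, covariate
  adjustment, dropout model or multiplicity handling.
* The packaged panel's question thresholds are placeholders (see above), so
  panel-fitted priors are illustrative, not reproductions; the calibrated
  prior is the reproduction route.
* The published scenario standard deviations (7.5–11.5 mm) sit far in the
  tail of the reconstructed variance prior; they are used verbatim anyway,
  as in the source analysis.
* Operating-characteristic proportions are Monte-Carlo estimates; at 1000
  trials their standard error is ≈ 0.006 near the null and ≈ 0.013 near
  0.78, and comparisons across implementations are meaningful only within
  that noise.
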