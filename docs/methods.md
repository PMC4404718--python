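# Methods

This note documents the models, the numerical choices, and the design
decisions behind `causalq`, in the order a user meets them.

## Causal-judgment models

All models consume a 2×2 contingency table of effect × cause counts and
emit a prediction on [0, 1].

**Parameterization.** A background cause of strength `w0 ∈ [0,1]` is always
present. A generative candidate of strength `w1` combines with it by
noisy-OR, `P(e|c) = w0 + w1 − w0·w1`; a preventive candidate by
noisy-AND-NOT, `P(e|c) = w0(1 − w1)`. In both cases `P(e|¬c) = w0`. The
null graph G0 fixes `w1 = 0`; G1 leaves it free. The preventive
parameterization is a design choice (noisy-AND-NOT is the standard
counterpart of noisy-OR); nothing else in the package depends on it.

**MLE.** The likelihood is a product of two binomials, so the MLE is
closed-form: `w0 = P̂(e|¬c)` and `w1` equals the causal-power statistic
`ΔP/(1 − P̂(e|¬c))` (generative) or `−ΔP/P̂(e|¬c)` (preventive). A
brute-force grid search over the likelihood is kept in the tests as an
independent check. Contingencies with `P̂(e|¬c) = 1` (generative) or `= 0`
(preventive) raise errors rather than returning infinities.

**Bayesian estimation.** Posteriors over `(w0, w1)` are computed by
trapezoid integration on a uniform grid over the unit square, default step
0.005 (201 nodes per axis). The step was chosen so that the G0/uniform
marginal likelihood matches the closed-form Beta function to relative error
well below 1e−4 and all reported predictions move by less than 1e−3 when
the step is halved; both checks run in the test suite and the acceptance
script. Two parameter priors are available:

- *uniform* — flat on the square;
- *Strong-and-Sparse (SS)* — unnormalized density
  `exp(−α·w0 − α·(1−w1))` for generative valence (strong candidate, weak
  background) and `exp(−α·(1−w0) − α·(1−w1))` for preventive (strong
  candidate, strong suppressible background), normalized on the grid.
  Default sharpness α = 5. The functional form and default follow the
  "strong and sparse" tradition of favoring deterministic single causes;
  α = 0 reduces exactly to the uniform prior, and posterior strength is
  monotone in α on strong contingencies (tested).

**Causal support / structure posterior.** `support = log m(G1)/m(G0)` with
`m(·)` the grid marginal likelihood under the graph; the structure
posterior weights the marginals by a structure prior (default
`P(G1) = 0.5` for both parameter priors, configurable — the SS structure
weights are not published).

**Structure induction.** The diagnostic query is Bayes' rule with a cause
base rate `P(c)`, default 0.5 to match the design (16 of 32 strands
exposed). Under G0 the diagnostic query equals `P(c)` and the predictive
query equals the G0-posterior mean of `w0`. The model's prediction is the
structure-posterior-weighted average of the two graph-conditional
posterior-mean queries, hence always a convex combination of them (tested
on every stimulus condition).

**Attribution.** `w1/(w0 + w1 − w0·w1)`, evaluated at the MLE or averaged
over the G1 parameter posterior. The `w0 = w1 = 0` grid corner, where the
ratio is undefined, carries zero posterior mass for any table with
effect-present observations and is excluded from the quadrature.

**The 16-variant registry.** {power, attribution, structure-induction
diagnostic, structure-induction predictive} × {MLE, Bayesian-uniform,
Bayesian-SS} plus {conditional diagnostic, conditional predictive} ×
{MLE, Bayesian-uniform}. Attribution and structure induction are defined
for generative causes only and contribute no preventive rows (their
preventive extensions are not established; the evaluation module logs the
exclusions). Two combinations needed definitions of our own:

- *structure induction × MLE*: the maximum-likelihood analog picks the
  graph with the higher maximized likelihood and evaluates the query at
  that graph's MLE. This preserves the family's structure-uncertainty
  flavor (the null graph can win for weak contingencies) without
  integration.
- *conditional models, Bayesian-uniform*: independent Beta(1,1) posteriors
  on `P(e|c)` and `P(e|¬c)`; the reported value is the posterior-mean
  (Laplace-smoothed) query.

## Beta GLM

**Likelihood.** `y ~ Beta(μφ, (1−μ)φ)` with `logit(μ) = x'b + u_j`,
`log(φ) = z'd`, `u_j ~ N(0, σ_u²)`. Ratings on [0, 100] are compressed to
the open interval by `y ↦ (y/100·(n−1) + 0.5)/n` with `n` the number of
analyzed responses — the standard transform for beta regression with
boundary observations; 50 maps to exactly 0.5 and the transform is
order-preserving.

**Coding.** Factors enter by effects coding: a k-level factor becomes k−1
indicator columns with the reference level (the first in the declared
order) coded −1 everywhere, so both intercepts estimate grand means.
Interactions are elementwise products of parent columns.

**Priors.** N(0, 10²) on every `b` and `d`; half-N(0, 2.5) on `σ_u`. These
are weakly informative on the logit/log scales; none of the reported
checks are sensitive to doubling the scales.

**Sampler.** Adaptive random-walk Metropolis within four Gibbs blocks —
`b` (joint), `d` (joint), `u` (per-subject, vectorized: the intercepts are
conditionally independent given the coefficients), `log σ_u`. Proposal
scales adapt toward a 0.2–0.5 acceptance rate during burn-in only, so the
retained chain uses a fixed kernel. Defaults are 8000 total draws with a
4000-draw burn-in; the seed is a required argument and identical seeds
yield bit-identical chains. A split-chain potential-scale-reduction
diagnostic and the block acceptance rates are logged with every fit.

**Summaries.** Posterior mean, SD and central 95% interval per parameter;
contrasts are linear combinations of draws summarized the same way, with
odds ratios reported as `exp(posterior-mean contrast)` rounded to 2
decimals — the point-estimate convention, not the posterior mean of
`exp(·)`.

**DIC.** `dbar` is the posterior-mean deviance, `pD = dbar − D(θ̄)` at the
posterior-mean parameters (Spiegelhalter's definition, including the
subject intercepts), `DIC = dbar + pD`. Differences are labeled negligible
(< 3), substantial (3–7), borderline (7–10) or definite (> 10).

## Synthetic data

**Stimuli.** Counts are the stated conditional probabilities × 16 strands
per set (exposed/unexposed, 32 total): generative C1 (0.50, 0.25), C2
(0.75, 0.50), C3 (0.75, 0.25) for (P(e|c), P(e|¬c)); preventive swaps the
two probabilities. The extracted frequency table disagrees with the stated
probabilities in the effect-column order; the probabilities are treated as
authoritative.

**Ratings.** Best estimates are drawn from the same beta GLM the analysis
fits, at the study's factor layout (Study 1: 38 generative + 35 preventive
subjects × 3 covariance × 3 questions = 657 records; Study 2A: four
between-subject cells at C3; Study 2B: 40-subject cue and 117-subject
no-cue arms, the latter with a Uniform(0,1) precedence-of-the-cause belief
entering the location predictor, default slope 2.25 on the logit scale).
Interval estimates are phenomenological, not a cognitive model: best ∓ a
half-width drawn as `60·Beta(2,4)/2` points, truncated to [0, 100], with a
3.3% fraction of pairs swapped to create invalid (min > max) records —
matching the removal rate the analyses assume (22 of 657). The default
generating coefficients mirror the published location/precision pattern
for Study 1 (grand mean ≈ 56, C3 above and C2 below the mean, predictive
questions least homogeneous, preventive ratings more homogeneous than
generative, σ_u = 0.57).

What the generator does **not** emulate: rounding to multiples of 5,
anchoring on earlier questions, order effects, dropout, or any response
process for the intervals. Passing round-trip tests therefore show that
the estimation machinery is correct and calibrated under the model's own
assumptions — not that the model is true of human raters.

**The dispersion-mechanism condition** (`dispersion_study_params`) is a
separate named truth used to demonstrate that rating heteroscedasticity
alone reorders model fit: question format manipulates only the precision
submodel (log-precision levels +1.0 / 0 / −1.0 for strength / structure /
predictive around a base of 1.4, i.e. raw rating SDs from ~15 to ~33
points), with question means held fixed. Fixing the means is what the
mechanism claims: for equal group means, each group's MSE is the squared
bias plus the rating variance, so the noisiest format is fit worst by
every deterministic model. The one-unit separation was sized by a
separation-to-noise analysis so that the induced ordering clears sampling
noise at a 73-subject design even for the variants with the largest bias
and the fewest applicable records (the generative-only families), and was
validated on simulation seeds disjoint from the test suite's.

## Evaluation

Ratings are divided by 100 and compared to predictions by squared error,
grouped by (variant, question, valence). Families that do not cover a
valence simply contribute no rows, and the exclusion count is reported.
Bootstrap CIs resample *subjects* with replacement (default B = 1000),
respecting the repeated-measures structure. Differences across question
formats are tested with the Friedman rank test on per-subject mean squared
errors (a chi-square statistic with k−1 df, no normality assumption;
invariant to monotone within-subject transforms); a Kruskal–Wallis variant
is available for independent groups. Degenerate input with every subject
tied across formats returns statistic 0, p = 1.

## Problem sizes and determinism

Everything is seeded explicitly; pipeline runs write a manifest with the
config hash. The test suite and the acceptance script use reduced problem
sizes chosen as the smallest that still separate signal from noise in each
check: parameter recovery on 603 records with 4000 retained draws,
null-interval coverage over 20 replications at 1500/500 draws, 20
replications of the dispersion mechanism, 500 replications of the Friedman
calibration. The full-scale sampler settings (8000/4000) remain the
library defaults.

## Known limitations

- The sampler is a single adaptive random-walk chain; for strongly
  correlated posteriors (heavily unbalanced designs, many interaction
  terms) it mixes slowly — check the logged split-R̂.
- Grid integration is exact enough at step 0.005 for 2×2 tables with tens
  of observations, but the cost grows quadratically with grid resolution;
  very large counts concentrate the posterior below the grid scale.
- The structure-induction × MLE and conditional-Bayesian variants are this
  package's own constructions (defined above); results for those cells are
  not comparable to other implementations without checking definitions.
- DIC is reported with Spiegelhalter's pD conditional on the random
  intercepts; alternative pD definitions shift DIC by a model-dependent
  constant and can change close comparisons.
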