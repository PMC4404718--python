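# causalq

Computational machinery for studying how **question formats shape causal
judgments**. The package implements, as a tested desk-scale pipeline:

- a zoo of **causal-judgment models** computed from 2×2 covariation data —
  causal power (noisy-OR / noisy-AND-NOT), Bayesian causal support and
  structure induction, conditional-probability models and causal
  attribution, each under maximum-likelihood, Bayesian-uniform and
  Bayesian Strong-and-Sparse estimation (16 variants in the default
  registry);
- a **Bayesian beta GLM** for bounded 0–100 ratings, with a logit *location*
  submodel and a log *precision* submodel, subject random intercepts,
  effects coding, MCMC estimation and DIC model comparison;
- a **synthetic rating generator** that emulates the three-study design this
  machinery targets (covariance × valence × question factors, interval
  estimates with occasional invalid min > max pairs, a
  precedence-of-the-cause belief covariate), since the human rating data are
  not public;
- **MSE model evaluation** by question format, with subject-level bootstrap
  CIs and Friedman rank comparisons — exposing the mechanism by which
  question formats with noisier ratings are fit worse by *every*
  deterministic model.

It is aimed at computational cognitive scientists comparing causal-reasoning
models, and at anyone who needs a compact, testable beta regression with a
dispersion submodel.

## The models in brief

For a candidate cause with strength `w1` and an always-present background
cause `w0`, the noisy-OR parameterization gives `P(e|c) = w0 + w1 − w0·w1`
and `P(e|¬c) = w0` (preventive: `P(e|c) = w0(1 − w1)`). Maximum-likelihood
estimation recovers the classical causal-power statistic
`ΔP / (1 − P(e|¬c))`. Bayesian estimation integrates over `(w0, w1)` on a
grid under a uniform or a Strong-and-Sparse prior
`exp(−α w0 − α(1 − w1))`; causal support is `log m(G1)/m(G0)`, the log
marginal-likelihood ratio of the graph with the candidate link against the
null graph. Structure induction predicts a diagnostic `P(c|e)` or predictive
`P(e|c)` query as the structure-posterior-weighted average of the
graph-conditional posterior-mean queries; attribution is
`w1 / (w0 + w1 − w0·w1)`.

Ratings `y ∈ (0,1)` are modeled as `Beta(μφ, (1−μ)φ)` with
`logit(μ) = x'b + u_subject` and `log(φ) = z'd`; a positive precision
coefficient means more homogeneous ratings (`Var = μ(1−μ)/(1+φ)`).

## Worked example

```
$ causalq generate --study S1 --seed 7 --out r.csv
wrote 657 records to r.csv
$ causalq predict --out p.csv
wrote 16 variants x 69 predictions to p.csv
$ causalq evaluate --predictions p.csv --ratings r.csv --bootstrap-b 200 --seed 7 --out mse.csv
Friedman chi2(2) = 4.96, p = 0.08379; wrote mse.csv
```

The 657 records are 73 subjects × 3 covariance conditions × 3 questions.
The prediction table has one row per model variant per condition × valence
cell (69 rows, not 96, because attribution and structure induction are
defined for generative causes only). For example:

```
variant,family,estimation,condition,valence,prediction
attribution:MLE,attribution,MLE,C3,generative,0.8888888888888888
```

is the attribution model's claim that, in the strong-contingency condition
(`P(e|c)=0.75, P(e|¬c)=0.25`), an observed effect was produced by the
candidate cause with probability 8/9. The MSE table scores every variant
against every subject's rating, per question and valence, with bootstrap
CIs:

```
  variant   question    valence    mse   n  ci_lower  ci_upper
power:MLE predictive generative 0.0545 103    0.0401    0.0683
power:MLE   strength generative 0.0505 111    0.0402    0.0622
```

and the Friedman statistic tests whether a model's fit differs across
question formats. In the Python API the same quantities come from
`causalq.causal_models`, `causalq.beta_glm`, `causalq.synthetic` and
`causalq.evaluation`; `causalq reproduce --seed 0 --out runs/` executes the
whole pipeline (scaled-down sampler sizes by default, `--full-scale` for
8000-draw chains).

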