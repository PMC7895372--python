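# Methods

This note documents the modelling and numerical choices behind `avbind`: the
observer models, the fitting procedure, what the synthetic cohorts do and do
not emulate, and the known limitations.

## Observer models

The representation is a single place-of-articulation axis per modality, with
B articulated front-most and G furthest back; D exists only as the middle
response region, which is how fused ("da") percepts arise from intermediate
posteriors. Working in one dimension is a deliberate simplification —
phoneme identification is surely multidimensional — but it keeps every
posterior closed-form.

Each cue contributes a Gaussian likelihood: one mean per consonant and
modality (4 parameters) and one variance per modality and SNR level
(6 parameters), with conditionally independent noise across modalities (zero
covariance in the bimodal likelihood). Three binding structures map a
bimodal stimulus to an auditory-axis posterior:

* **MLE**: mandatory fusion, inverse-variance weighting.
* **Joint Prior**: a Gaussian ridge prior along the A = V diagonal, with
  cross-diagonal variance σ²_o. Marginalising the bimodal posterior onto the
  auditory axis gives a Gaussian with mean w_A μ_A + (1 − w_A) μ_V and
  variance w_A σ²_A, where w_A = (2σ²_o + σ²_V)/(2σ²_o + σ²_V + σ²_A).
* **BCI**: a two-component mixture — the forced-fusion posterior with weight
  1 − P(C = 2) and the auditory marginal with weight P(C = 2). The mixing
  weights are the *fitted prior* probabilities, one per synchrony condition,
  not trial-wise posterior causal probabilities: the model predicts one
  response distribution per condition (count data), so a per-trial posterior
  weighting has nothing to condition on.

Read-out truncates the posterior to a finite interval and cuts it at two
boundaries; each category's probability is the component-wise truncated and
renormalised mass (mixtures average their components' renormalised masses).
Tails outside the interval are discarded, not lumped into the end
categories.

### Fixed constants and identifiability

The representation interval is fixed to [0, 1] and is not fitted. The model
family is invariant under affine maps of the axis (means, boundaries and
√variances transform together), so the scale must be pinned somewhere;
pinning the interval resolves it and keeps all position parameters
interpretable as fractions of the representational range. One shared
boundary pair serves all conditions and both unimodal report tasks — the two
boundary parameters are the only read-out parameters. Free-parameter counts
are therefore 12 (MLE), 13 (Reduced: one free binding parameter, the
asynchronous one), 14 (Full: one per synchrony condition).

## Fitting

The objective is the multinomial negative log-likelihood of the per-condition
counts (the parameter-independent multinomial coefficient is dropped) plus a
precision penalty λ·(Σ 1/σ²_A + Σ 1/σ²_V) over the six sensory variances,
λ = 7 by default. The penalty is linear in the precisions. Without it the
optimiser can push a variance toward zero, making predictions needle-sharp
and the fit unstable. Only the variances are penalised; means, boundaries
and binding parameters are free.

Optimisation runs on an unconstrained vector: scaled-logit means and
boundaries (the second boundary via a positive-gap transform, so any real
vector yields 0 < b₁ < b₂ < 1), log variances, log σ²_o, logit P(C = 2).
Every restart uses L-BFGS-B with numerical gradients (maxiter 400,
ftol 1e-10, gtol 1e-6); starting points are uniform on documented ranges of
the unconstrained scale (means ≈ (0.08, 0.92) on the axis, variances
(1e-3, 0.5), binding variances (1e-3, e), P(C = 2) (0.02, 0.98)), with the
restart sequence derived deterministically from the configuration seed. The
restart with the lowest penalised objective wins. Inside the training
objective predicted probabilities are floored at 1e-9 before the log.

Cross-validation leaves out one condition per fold (42 folds), fits on the
rest and predicts the held-out condition. Held-out error is the RMSE over
all 42 × 3 (condition, category) cells between predicted probabilities and
observed proportions — RMSE rather than log-likelihood because a held-out
cell can legitimately receive probability 0. Two run profiles exist:
`paper` (100 restarts, full restarts per fold) and `test` (20 restarts for
the full-data fit; each fold warm-started from the full-data optimum plus
one random restart). The test profile is what the package's own test suite
and acceptance script use; it keeps a full 42-fold CV of one subject and
variant near ten seconds on one CPU. The λ sweep evaluates mean CV RMSE
over subjects and variants on a grid (default log-spaced on [1e-3, 1e2])
and selects the minimiser.

### Numerical details

* Gaussian interval masses use mirrored-CDF segment differences: a segment
  entirely in the upper tail is computed as ndtr(−z₁) − ndtr(−z₂) rather
  than ndtr(z₂) − ndtr(z₁), which cancels catastrophically once both values
  round to 1. Without this, posteriors far outside the interval (legal
  during optimisation and in segregation limits) lose all relative mass
  information.
* A posterior whose total interval mass is below 1e-300 raises a
  degenerate-posterior error in the reference API; inside the vectorised
  training objective the mass is floored instead, so a bad restart is
  penalised rather than fatal.
* The vectorised engine used in the optimisation loop is tested for exact
  agreement with the per-condition reference implementation across all
  variants.
* Exp/log transforms clip their argument at ±40, bounding variances to
  (≈4e-18, ≈2e17) and keeping every unconstrained vector finite-valued.

## Synthetic cohorts

`simulate_subject` draws, for each condition, a multinomial with the
design's repetition count and the observer's predicted category
probabilities — i.e. data are generated by exactly the process the models
assume. `simulate_cohort` adds between-subject heterogeneity as Gaussian
perturbations (sd 0.25 by default) of the group parameter vector on the
unconstrained scale, which keeps every subject's parameters valid without
clipping; pinned parameters stay pinned.

The default group observer is a Reduced Joint Prior: category means 0.10/0.90
(auditory B/G) and 0.10/0.80 (visual; visual "ga" is less distinctive from
"da" than the acoustic velar burst, so its mean sits nearer the D region),
variances 0.005/0.02/0.08 (auditory high/mid/low SNR) and 0.003/0.02/0.10
(visual — clear video is the most reliable cue), boundaries 1/3 and 2/3,
synchronous binding variance pinned at 0 and asynchronous σ²_o = 0.05.
These defaults were chosen once so that the *expected* response
probabilities show the paradigm's qualitative signatures, which the test
suite asserts: a strong McGurk effect for synchronous incongruent stimuli,
its release by a 500 ms audio lead, fewer auditory reports as auditory SNR
drops and more as visual SNR drops.

What the simulations do **not** emulate: lapses and response biases, learning
or fatigue across blocks, any violation of the conditional-independence or
shared-boundary assumptions, and consonant-specific sensory precisions.
Real observers violate several of these (the shared precision-per-SNR
assumption visibly misfits unimodal extremes), so passing recovery tests
shows the pipeline is correct and well-posed under its own assumptions —
not that the model family is an adequate description of human data.

## Evaluation conventions

Paired model contrasts use Wilcoxon signed-rank tests with zero differences
dropped and the exact small-sample null (scipy's implementation, itself
cross-checked in the tests against brute-force sign-flip enumeration).
Binding-parameter tests against zero are one-sided one-sample t-tests on
the asynchronous parameter; a cohort with literally zero spread is flagged
degenerate instead of tested. Precision-ordering tests are one-sided paired
signed-rank tests of high > mid and mid > low per modality. The Joint Prior
vs BCI contrast is two-sided. No multiple-testing correction is applied
anywhere. Auditory weights are defined for the Joint-Prior family only
(MLE being the σ²_o = 0 case); BCI posteriors are mixtures and have no
single fused weight.

## Problem sizes

The package's own simulations use: recovery — 8 subjects at 500 repetitions
per condition, test-profile fitting; model recovery — two 8-subject cohorts
(binding-release truth and forced-fusion truth) at the study's 25
repetitions, CV for ReducedJP and MLE; oracle suites — 100 random read-out
instances and 50 random binding-limit draws. These sizes are the package's
choice of a desk-scale harness; the `paper` profile exposes the full
published procedure (16 subjects, 100 restarts, full restarts per fold) for
users who want it.

## Known limitations

* **Penalty scale.** With the representation interval fixed to [0, 1],
  realistic variances are small (0.003–0.1), so their precisions are large
  (10–330) and the λ = 7 penalty is a strong prior: fitted variances are
  systematically inflated relative to ground truth, and absolute CV RMSE on
  25-repetition cohorts is around 0.2. Model *comparison* is unaffected
  (all variants carry the same penalty), and auditory weights — ratios of
  variances — are recovered with a median absolute error of about 0.05 at
  500 repetitions, but users who care about absolute variance estimates
  should sweep λ on their own data rather than trust the default.
* **Fixed-weight BCI.** The BCI variant weights its two branches by fitted
  prior probabilities per synchrony condition; a trial-wise posterior-weighted
  variant is a different model and is not implemented.
* **No hierarchy.** Subjects are fitted independently; there is no partial
  pooling across the cohort.
* **Three-category read-out.** With only interval masses observable, unimodal
  vs bimodal posterior shape (Joint Prior vs BCI) is weakly identified;
  expect the two families to tie on realistic data.
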