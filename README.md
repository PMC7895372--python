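# avbind

Bayesian binding-and-fusion observer models for audiovisual syllable
identification.

When we watch a speaker, what we *hear* depends on what we *see*: congruent
lip movements enhance the perception of noisy speech, and incongruent ones
can change it outright — dubbing an auditory "ba" onto a visual "ga" often
yields the illusory percept "da" (the McGurk illusion). Bayesian accounts
split this into a **binding** stage (should the two cues be attributed to a
common cause?) and a **fusion** stage (how should bound cues be weighted by
their reliability?). `avbind` implements and compares observer models that
separate these stages, for three-alternative (B / D / G) identification data
from a design that manipulates binding (audiovisual asynchrony) and fusion
(auditory and visual signal-to-noise ratio) at the same time.

## Models

All models live on a one-dimensional place-of-articulation axis confined to
[0, 1]. Each cue is a Gaussian likelihood with a mean per consonant (μ_A,B,
μ_A,G, μ_V,B, μ_V,G) and a variance per SNR level (σ²_A, σ²_V for
high/mid/low), with independent sensory noise across modalities. Because the
observer reports what they heard, the bimodal posterior is marginalised onto
the auditory axis:

* **MLE (forced fusion)** — inverse-variance weighting, mandatory binding:
  μ_AV = w_A μ_A + (1 − w_A) μ_V with w_A = σ²_V / (σ²_V + σ²_A).
* **Joint Prior** — a Gaussian "binding ridge" prior along the A = V diagonal
  with cross-diagonal variance σ²_o couples the cues softly:

      w_A = (2σ²_o + σ²_V) / (2σ²_o + σ²_V + σ²_A),
      μ_AV = w_A μ_A + (1 − w_A) μ_V,   σ²_AV = w_A σ²_A.

  σ²_o = 0 recovers the MLE; σ²_o → ∞ segregates the cues completely.
* **BCI (Bayesian causal inference)** — a mixture of the forced-fusion
  posterior and the auditory marginal, weighted by the probability of
  separate causes P(C = 2).

Responses are read out by truncating the posterior to the unit interval and
applying two boundaries b₁ < b₂: mass below b₁ → "B", between → "D", above
b₂ → "G". *Reduced* variants pin the binding parameter to full fusion for
synchronous stimuli and release it only for asynchronous ones; *Full*
variants fit one binding parameter per synchrony condition. Free-parameter
counts are 12 (MLE), 13 (Reduced) and 14 (Full).

Fitting minimises the multinomial negative log-likelihood of the per-condition
response counts plus a precision penalty λ·Σ(1/σ²) over the six sensory
variances (λ = 7 by default), with L-BFGS multi-start over an unconstrained
parameterization. Model comparison uses leave-one-condition-out
cross-validation (42 folds), scored as RMSE between predicted probabilities
and observed proportions, with paired Wilcoxon signed-rank contrasts across
subjects.

A synthetic-data module simulates subjects and cohorts with the study's
structure (16 subjects × 42 conditions × 25 repetitions), so the whole
pipeline is testable without behavioural data files.

## Worked example

```python
from avbind import (CohortSpec, FitConfig, cross_validate, enumerate_design,
                    extract_auditory_weights, fit_model, simulate_cohort)

design = enumerate_design()                      # the 42-condition design
cohort, truths = simulate_cohort(CohortSpec(n_subjects=2, seed=7), design)
config = FitConfig.profile("test", seed=3)       # 20 restarts, warm-started CV

subject = cohort[0]
for variant in ("MLE", "ReducedJP"):
    cv = cross_validate(subject, variant, design, config)
    print(f"{variant:10s} held-out RMSE = {cv.rmse:.4f}")

fit = fit_model(subject, "ReducedJP", design, config)
print(f"async binding variance sigma_o2 = {fit.params.prior.value_async:.4f}")
wt = extract_auditory_weights(fit, design).table
print(wt[wt.pairing == "mcgurk"]
      .pivot_table(index=["auditory_snr", "visual_snr"], columns="soa", values="w_A")
      .round(3))
```

prints

```
MLE        held-out RMSE = 0.2303
ReducedJP  held-out RMSE = 0.2089
async binding variance sigma_o2 = 0.1156
soa                      async   sync
auditory_snr visual_snr
high         high        0.812  0.581
             low         1.000  1.000
             mid         1.000  1.000
low          high        0.317  0.130
mid          high        0.554  0.286
```

The binding-release model (ReducedJP) predicts the held-out conditions better
than forced fusion (lower RMSE), its fitted asynchronous binding variance is
well above zero, and the auditory weights behave as the model family demands:
they rise with relative auditory reliability (up each column) and are always
higher for asynchronous than synchronous presentations of the same stimulus
(weaker binding → the report follows the auditory cue).

There is also a command-line interface:

```sh
avbind simulate --n-subjects 4 --seed 1 --out trials.csv
avbind crossval trials.csv --variant MLE --variant ReducedJP --out cv.csv
avbind run --config run.json
```

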