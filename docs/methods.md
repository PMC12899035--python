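# Methods

This note records the models behind `stabsense`, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Problem setting

Ethanol stability (ES) is a binary intake quality gate: a raw-milk batch
is *unstable* (label 1) if it coagulates when mixed 1:1 with aqueous
ethanol. The package estimates ES from 15 routinely measured intake
indicators. Three prevalence regimes matter:

* **curated** (~20% positive) — the balanced analysis set used for
  feature-relevance work (one positive per four sampled negatives);
* **cleaned** (~1:63) — what survives cleaning of a full intake export;
* **production** (~0.09%) — raw production volume, where a trivial
  all-negative classifier exceeds 99% accuracy and precision collapses for
  any realistic screen. Recall on the unstable class is the deployment
  metric.

## Synthetic cohort generator

Real intake data are confidential, so `stabsense.cohort` generates
cohorts with the structure the method relies on:

* **Marginals.** Each indicator has class-conditional Gaussian (or
  Bernoulli) marginals at typical bovine-milk values: Protein 3.25 ± 0.15,
  Fat 3.90 ± 0.35, SNF 8.70 ± 0.25 g/100 g, Acidity 13 ± 0.8 °T,
  Lactose 4.60 ± 0.15 g/100 g, RD 1.030 ± 0.0015, MTemp 6 ± 1.2 °C, plus
  count-type indicators (TVC, SCC, Psychro) truncated at zero and two
  binary contaminant flags (AD1/AD2). No published per-indicator moments
  exist for the original industrial data, so these are calibration
  choices, configurable via `FeatureProfile`.
* **Structure.** Total solids are generated structurally,
  `TS = Fat + SNF + N(0, 0.05)`, and the latent Fat–SNF correlation is
  solved (Brent root-finding) so that the cohort-level Pearson
  correlation r(Fat, TS) equals a configurable target, 0.92 by default.
  One mechanism therefore produces both the dairy mass-balance identity
  and the strong Fat–TS correlation.
* **Class signal.** The eight informative indicators (Protein, TS, SNF,
  Fat, Acidity, Lactose, RD, MTemp) receive class-conditional mean shifts
  of `effect_scale` standard deviations (direction per indicator:
  unstable milk runs lower in protein, solids, lactose, density and
  acidity and arrives warmer). The default `effect_scale = 2.0` was fixed
  analytically before any classifier was trained: it puts the two-class
  Mahalanobis distance at ≈5.0, i.e. a per-class Bayes error of ≈0.6%,
  so a competent classifier can reach >90% recall — the package's
  stand-in for the clear latent-space class separation observed in real
  intake data. The remaining seven indicators carry no class signal.
* **Exact composition.** The number of positives is
  `round(n × prevalence)` by construction (not a binomial draw), so
  dataset-composition arithmetic is deterministic.
* **Messiness.** `inject_messiness` reproduces raw-export pathologies:
  a configurable fraction of blank cells, syntactically non-numeric junk
  strings ("n/a", "<LOD", ...), and text labels "positive"/"negative".

**What the generator does not emulate:** seasonal and long-term drift,
multimodal marginals (the real relative-density distribution is strongly
multimodal), inter-farm heterogeneity, measurement autocorrelation across
batches, and label noise. Passing tests on these cohorts therefore
demonstrates the pipeline's correctness and its behaviour under the
assumed statistical structure — not performance on any real dairy stream.

## Cleaning

Cleaning is row-atomic: a record with any blank or unparseable cell is
dropped whole, keeping retained records internally consistent (no
imputation). Cells are parsed after stripping whitespace and trailing unit
suffixes; "positive"/"negative" (case-insensitive) map to 1/0 in the label
and AD columns; any other non-numeric token removes the row. Output tables
put the label first and preserve the original indicator order, and CSV
round trips are exact (`float_precision="round_trip"` on load).

## Feature relevance and selection

Two views are combined:

* **Explicit:** one-way ANOVA F, point-biserial correlation, random-forest
  impurity importance (200 trees, importances sum to 1) and logistic
  coefficients per indicator, plus the Pearson heatmap over the 13
  continuous indicators. Only the logistic fit sees standardized features
  (coefficient comparability); the other statistics are scale-equivariant
  or scale-free. Zero-variance indicators are flagged and reported as NaN
  rather than raising.
* **Implicit:** a symmetric MLP autoencoder (15 → 32 → k → 32 → 15, ReLU,
  MSE, Adam) fitted for k ∈ {2..5}. The latent dimension is chosen by an
  **elbow rule** on held-out reconstruction error: the smallest k whose
  successor no longer halves the error. A one-standard-error rule was
  tried first and rejected: once several dimensions reach the optimization
  noise floor, per-sample-error standard errors are far smaller than
  run-to-run optimization noise, and the rule failed to recover a planted
  3-dimensional subspace; the elbow rule recovered it in every trial.
  Each latent coordinate is summarized (mean, sd, skewness), its
  "composition" is the top-5 features by |Pearson r| with the coordinate
  (a decoder-weight ranking would be the alternative; correlation was
  chosen because it is architecture-agnostic), and its class separation
  is the |point-biserial| correlation with the label.

The selection policy keeps a feature that ranks in the top 8 of at least
3 of the 4 explicit statistics, or appears in the composition of the most
class-separating latent. On the calibrated cohort this reproduces exactly
the eight informative indicators.

## Constrained tabular diffusion

* **Schedule:** linear β from 1e-4 to 0.02 over T = 1000 steps (cosine
  available). `ᾱ_T < 1e-3`, so the terminal distribution is effectively
  the prior.
* **Denoiser:** MLP (input = noised features ⊕ 16-dim sinusoidal timestep
  embedding; hidden 128-128, ReLU) predicting ε for continuous columns
  (MSE) and the original category per categorical column (cross-entropy).
  Trained 1000 epochs, batch 256, AdamW at 1e-3 with cosine annealing —
  deliberately the same budget whether the positive set has 200 or 842
  records, since one epoch is then only a handful of steps.
* **Sampling:** standard ancestral reverse diffusion. Categorical blocks
  are resampled from the exact reverse kernel — the mixture over original
  categories c of the per-category posteriors
  `θ_c ∝ (α_t x_t + (1−α_t)/K) ⊙ (ᾱ_{t−1} e_c + (1−ᾱ_{t−1})/K)`,
  weighted by the predicted `p(x₀ = c | x_t)`. The common shortcut of
  plugging the mean x̂₀ distribution inside the product was tried first
  and rejected: an oracle simulation (closed-form x̂₀ posterior, K = 2,
  marginal 0.30) showed it biases generated frequencies toward uniform
  (0.39 recovered), while the mixture form is unbiased (0.301).
* **Constraints:** strict positivity of all selected indicators and
  `|TS − (Fat + SNF)| ≤ 0.5` in native units (g/100 g percentage points);
  0.5 *absolute* units is used rather than a relative 0.5%, matching the
  executed augmentation setting, and is configurable. Whole candidate
  records violating either constraint are discarded and regenerated
  (re-drawing whole records rather than single features keeps the joint
  distribution intact); the attempt budget defaults to 100× the target
  count and exhaustion raises an error carrying per-constraint violation
  frequencies. In practice acceptance is near 100% once the denoiser has
  learned the Fat+SNF≈TS structure.
* **Composition:** the augmented training set contains each real positive
  twice (original + duplicate, reinforcing the real distribution), four
  generated positives per real one, and three negatives per positive —
  with 842 real positives this yields 5052 positives and 15156 negatives.
  Counts are validated and a `source` column tracks provenance.

## Attentive classifier

Architecture per decision step: input batch-norm → feature transformer
(2 shared + 2 step-specific GLU blocks, width n_d + n_a, residuals scaled
by √0.5) → split into decision (n_d) and attention (n_a) parts; attentive
transformer = linear map n_a → d whose scores, multiplied by the running
prior, pass through **sparsemax** (exact simplex projection, computed by
the sort-based algorithm; backward pass uses the closed-form Jacobian).
Prior update: `prior ← prior ⊙ (γ − M)`. ReLU'd decision outputs are
summed into the final linear logit; the per-sample aggregate feature
importance weights each step's mask by that step's total decision output.

Loss = binary cross-entropy + λ_sparse × mean per-step mask entropy
(zero iff all masks are one-hot). Tuned defaults: n_d = 62, n_a = 20,
3 steps, λ_sparse = 0.026, learning rate 0.012 (cosine-annealed AdamW),
batch 58.

Two coefficients deserve care:

* `reg_coef = 0.038` is the general regularization strength, implemented
  as decoupled weight decay in AdamW; its natural search range is
  1e-3–1e-1.
* `gamma = 1.3` is the sparsemax prior-relaxation coefficient, whose
  conventional range starts at 1 (γ = 1 bars a fully used feature from
  later steps). Values far below 1 drive priors negative and empirically
  stall optimization on separable data, which is why the two roles are
  kept distinct rather than conflated into one "regularization" knob.

Plain batch normalization is used (training statistics during fit, frozen
running statistics at inference; ghost batch norm is pointless at batch
58). The decision threshold is fixed at probability 0.5 — imbalance is
handled by augmentation, not reweighting or threshold tuning. Training
keeps the best-validation-loss checkpoint with early stopping
(patience 15). Baselines: a 2-hidden-layer MLP with early stopping and
gradient-boosted trees (500 trees, depth 6, learning rate 0.1).

Hyperparameter search is a seeded random search over the documented space
(log-uniform for rates and coefficients), maximizing a user-supplied
objective (validation F1 by default in examples); failed trials are
logged and skipped.

## Evaluation and pipeline

Metrics come from explicit confusion counts; undefined precision/recall
(no predicted or true positives) is reported as 0 with a `degenerate`
flag so classifier collapse is visible instead of an exception. The
pipeline evaluates on (a) the stratified 64/16/20 train/valid/test split
of the augmented cohort ("curated_test") and (b) a freshly generated
cohort at production prevalence; a `production_reuse` flag instead scores
the full cleaned cohort, which shares rows with training data — the
non-disjoint evaluation mode some industrial settings force — and is
labelled as such in reports. Stability runs repeat the full pipeline over
seeds; sensitivity sweeps vary one classifier hyperparameter with
everything else fixed, validating values before any training.

## Problem sizes

The default pipeline cohort is 13,440 records at 1:63 prevalence
(≈210 positives before messiness), scaled so that a full run — cohort,
cleaning, dual relevance analysis, diffusion training and sampling,
classifier training and both evaluations — completes in well under a
minute on one CPU core while preserving every structural property of the
workflow (imbalance ratio, 1:4 curated base, 1:1:4 real:duplicate:generated
positive composition, 3:1 negatives). The constraint-enforcement check
uses the full published minority-class size (842 real positives, 3,368
generated). Test-suite fits use further reduced budgets (fewer epochs,
shorter schedules) chosen to keep each property detectable.

## Known limitations

* The synthetic cohorts are unimodal and stationary; conclusions about
  real intake streams require re-validation (see generator caveats).
* The diffusion model is unconditional on the class label — it is trained
  on positives only, which is sufficient here because only the minority
  class is generated.
* Probabilities are not calibrated; the 0.5 threshold is a convention.
* The numpy autodiff core is single-threaded and eager; it is sized for
  this package's models, not a general training framework.
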