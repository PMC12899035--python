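# stabsense

Soft sensing of **raw-milk ethanol stability** from routine physicochemical
intake indicators.

Ethanol stability — the resistance of milk protein colloids to coagulation
when mixed 1:1 with aqueous ethanol — is a key intake quality gate in dairy
processing, but the assay is destructive and manual. Dairy plants already
measure a battery of indicators at intake (protein, fat, total solids,
solids-not-fat, acidity, lactose, relative density, milk temperature, cell
and microbial counts, ...). `stabsense` turns those routine measurements
into a predictive screen for the rare *ethanol-unstable* batches.

The hard part is extreme class imbalance: unstable batches are ~1:63 of
cleaned intake records and ~0.09% of raw production volume. The package
addresses this with a constraint-aware **tabular denoising diffusion
model** that enriches the minority class, and a **sparsemax-attentive
tabular classifier** (TabNet-style) trained on the augmented data.

Because real intake data are proprietary, the package ships a first-class
synthetic cohort generator that reproduces the statistical structure the
method assumes, so the entire workflow is testable offline.

## What's inside

| stage | module | core objects |
|---|---|---|
| synthetic cohorts | `stabsense.cohort` | `CohortSpec`, `generate_cohort`, `inject_messiness` |
| raw-export cleaning | `stabsense.cleaning` | `clean_table`, `CleanTable`, CSV round trip |
| feature relevance | `stabsense.relevance` | `explicit_relevance`, `MilkAutoencoder`, `select_features` |
| minority-class augmentation | `stabsense.diffusion` | `TabularDiffusionGenerator`, `check_constraints`, `compose_augmented` |
| classifier + baselines | `stabsense.tabnet` | `TabNetClassifier`, `sparsemax`, `hyperparameter_search` |
| evaluation & orchestration | `stabsense.evaluation`, `stabsense.pipeline` | `evaluate`, `stability_runs`, `run_pipeline` |

### The models in brief

**Forward diffusion.** Continuous features (z-scored) are corrupted by a
Markov chain `x_t = √α_t · x_{t−1} + √(1−α_t) · ε_t` with `α_t = 1 − β_t`,
equivalently `x_t = √ᾱ_t · x_0 + √(1−ᾱ_t) · ε` with `ᾱ_t = ∏_{i≤t} α_i`.
Categorical features follow the multinomial analogue
`q(x_t|x_{t−1}) = Cat((1−β_t)·x_{t−1} + β_t/K)`. A small MLP conditioned on
a sinusoidal timestep embedding predicts the added noise (MSE) and original
categories (cross-entropy). During ancestral reverse sampling, candidates
violating either dairy-chemistry constraint — strict positivity of the
selected indicators, and `|TS − (Fat + SNF)| ≤ 0.5` g/100 g — are rejected
and regenerated, so every delivered record is physically plausible.

**Attentive classifier.** At each decision step, an attentive transformer
produces a per-sample feature mask `M = sparsemax(prior ⊙ h(a))`, where
sparsemax is the Euclidean projection onto the probability simplex and the
prior is relaxed via `prior ← prior ⊙ (γ − M)`. ReLU'd decision outputs
are aggregated across steps into the logit; mean mask entropy is the
sparsity penalty weighted by `λ_sparse` in the loss. Masks give instance-
wise feature attribution — *why* a given batch was flagged.

The neural components run on a compact numpy reverse-mode autodiff core
(`stabsense._autograd`) with AdamW and cosine learning-rate annealing.

## Worked example

```python
from stabsense import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, outdir="runs/demo"))
print(result.selected_features)
t = result.eval_test
print(f"accuracy {t.accuracy:.4f}  precision {t.precision:.4f} "
      f"recall {t.recall:.4f}  f1 {t.f1:.4f}")
p = result.eval_production
print(f"production: accuracy {p.accuracy:.4f}  precision {p.precision:.4f} "
      f"recall {p.recall:.4f}")
```

prints (seed 1):

```
['Protein', 'TS', 'SNF', 'Fat', 'Acidity', 'Lactose', 'RD', 'MTemp']
accuracy 0.9892  precision 0.9854 recall 0.9712  f1 0.9782
production: accuracy 0.9947  precision 0.1447 recall 0.9783
```

Reading this: the dual relevance analysis (four explicit statistics plus
autoencoder latents) recovers the eight informative indicators; on the
held-out test split of the augmented cohort the classifier catches 97% of
unstable batches with hardly any false alarms. On a fresh cohort at
production prevalence (0.09% unstable) accuracy is trivially high and
precision collapses even though recall holds — the expected behaviour under
extreme imbalance, which is why recall is the deployment metric that
matters.

The same stages are scriptable from a shell:

```bash
stabsense generate --out cohort.csv --seed 1 --messy
stabsense clean    --in cohort.csv --out clean.csv
stabsense select   --in clean.csv  --out features.json
stabsense augment  --in clean.csv  --features features.json --out augmented.csv
stabsense run      --outdir runs/full --seed 1
```

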