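# omicforest

Multi-weighted deep forests for staging-style classification of
small-sample, high-dimensional multi-omics feature tables.

## The problem and the model

Molecular staging cohorts are awkward for deep learning: a few hundred
patients, tens or hundreds of thousands of features, several data
modalities per patient (DNA methylation beta values, RNA-seq expression,
copy-number calls), and ordered, imbalanced class labels.  Deep forest
(gcForest-style) cascades handle this regime well, but the standard
architecture treats all of its parts as equal: every scanning forest and
every sliding-window granularity contributes identically to the class
vectors, and modalities are modelled separately or naively concatenated.

`omicforest` implements a multi-weighted variant of the architecture:

* **Multi-grained scanning with weighted forests.**  A raw M-dim feature
  vector is cut into V = (M − L)/S + 1 sliding windows per granularity L.
  Window instances train one random forest and one completely random
  forest; their concatenated per-window class-probability vectors (length
  2·V·C for C classes) are scaled by weights α₁, α₂ obtained by
  normalizing the forests' out-of-bag **HUM** — the hypervolume under the
  ROC manifold, the C-class generalization of AUC (the probability that a
  one-per-class tuple of samples is concordantly classified):
  α₁ = HUM₁/(HUM₁+HUM₂).
* **Window weights by sorting optimization.**  For each sample, the mean
  of the top 1/C fraction of its descending-sorted class vector
  approximates how confidently a window predicts it; averaging over
  samples gives the window's ability W_t, and β_t = W_t / Σ W normalizes
  these into per-granularity weights applied to the scan vectors.
* **Cascade forest.**  Layer 1 trains on the first window's vector; each
  later layer trains on the previous layer's 4·C augmented class vector
  (two random + two completely random forests) concatenated with the next
  window's vector, cycling through granularities.  Augmented vectors for
  training are produced by in-layer k-fold cross-fitting; growth stops
  when validation accuracy stops improving.  Prediction averages the last
  layer's four probability vectors.
* **Decision-level fusion.**  One model per modality; fused class score
  H(x) = argmax_q Σ_p γ_p h_p^q(x) with γ_p the modality models'
  validation accuracies normalized to sum to 1.
* **Nested cross-validation.**  Outer folds estimate the error; inner
  folds per modality refit feature selection (L1/lasso, to an exact
  retained count), set the cascade depth by early stopping, and measure
  the accuracies that become γ.

A synthetic-data module generates three-modality cohorts with a shared,
ordered latent class signal so the whole pipeline is testable end to end
without any external download.

## Worked example

```python
import numpy as np
from omicforest import CascadeForest, MultiGrainedScanner, window_count

M, windows, C = 400, [100, 200, 300], 3
print(window_count(M, 100, 1))          # 301 window positions at L=100

rng = np.random.default_rng(1)
y = np.repeat([0, 1, 2], 4)
X = rng.normal(size=(12, M)); X[:, :40] += 2.0 * y[:, None]

scan = MultiGrainedScanner(window_lengths=windows, n_trees=5, seed=1).fit_transform(X, y)
print([b.shape[1] for b in scan.per_window])   # [1806, 1206, 606]

cascade = CascadeForest(n_trees=5, kfold_k=2, fixed_depth=4, seed=2).fit(scan, y)
print(cascade.input_dims_)                     # [1806, 1818, 1218, 618]
```

The scan vector lengths are 2·V·C (e.g. 2·301·3 = 1806); each cascade
layer emits a 4·C = 12-dim augmented vector, so layer 2 consumes
12 + 1806 = 1818 dims, layer 3 consumes 12 + 1206 = 1218, layer 4
consumes 12 + 606 = 618.  See `examples/` for narrative scripts covering
simulation, HUM weighting, single-modality training, and the fused
nested-CV evaluation, and `docs/methods.md` for the full model
description and design choices.

## Command line

```bash
omicforest simulate --seed 7 --out data/            # synthetic cohort
omicforest select-features --input data/rna.csv --labels data/labels.csv \
    --target-count 320 --out data/rna320.csv
omicforest evaluate --config run.yml --out report.json   # nested CV
omicforest train --config run.yml --out fused.model
omicforest predict --model fused.model --inputs rna=data/rna.csv \
    --inputs methylation=data/methylation.csv --inputs cnv=data/cnv.csv \
    --out predictions.csv
```

`run.yml` holds the input paths, a mandatory master seed, and the model
parameters (windows, tree counts, fold counts, stopping tolerance);
unknown keys are rejected and every run writes a manifest with the config
hash, seed and library versions.

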