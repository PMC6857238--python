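"""Train one weighted deep forest on a single modality and inspect it.

Fits lasso selection -> weighted multi-grained scanning -> cascade on a
synthetic RNA-like table, with early stopping on a held-out validation
split, and reports the learned weights and holdout accuracy.
"""

import numpy as np

from omicforest import SimSpec, WeightedDeepForest, generate
from omicforest._folds import stratified_folds

res = generate(
    SimSpec(
        n_per_class=(30, 30, 30),
        dims=(120, 120, 39),
        n_informative=(20, 20, 8),
        effect_size=2.0,
        seed=5,
    )
)
X = res.feature_matrices["rna"].values
y = res.labels.labels

(train, test), _ = stratified_folds(y, 3, seed=0)[:2]
(fit_idx, val_idx) = stratified_folds(y[train], 4, seed=1)[0]

model = WeightedDeepForest(
    n_trees_scan=50, n_trees_cascade=50, select_target=60, seed=7
)
model.fit(X[train][fit_idx], y[train][fit_idx], X[train][val_idx], y[train][val_idx])

print("selected features:", len(model.selected_), "of", X.shape[1])
print("window lengths:", model.scanner_.lengths_)
print("window weights beta:", np.round(model.scanner_.beta_, 3))
for fp in model.scanner_.forest_pairs_:
    print(
        f"  L={fp.spec.length:3d}: OOB HUM (rf, crf) = "
        f"({fp.oob_hum[0]:.3f}, {fp.oob_hum[1]:.3f}) -> alpha = "
        f"({fp.weights.alpha1:.3f}, {fp.weights.alpha2:.3f})"
    )
print("cascade depth:", model.cascade_.best_depth_, "val scores:", model.cascade_.val_scores_)

acc = float(np.mean(model.predict(X[test]) == y[test]))
print(f"holdout accuracy: {acc:.3f} (chance 0.333)")
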