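"""Walk through the multi-grained scanning and cascade dimensions.

With a 400-dim input, windows (100, 200, 300) at stride 1 and 3 classes:
each window t yields V_t = (400 - L_t) + 1 positions and a 2*V_t*3 class
vector per sample (two forests x V windows x 3 classes); the cascade's four
forests emit a 12-dim augmented vector, so the layer inputs run
1806 -> 1818 -> 1218 -> 618.
"""

import numpy as np

from omicforest import CascadeForest, MultiGrainedScanner, window_count

M, windows, C = 400, [100, 200, 300], 3
for L in windows:
    V = window_count(M, L, 1)
    print(f"window L={L}: V={V} positions -> class vector length 2*{V}*{C} = {2*V*C}")

rng = np.random.default_rng(1)
y = np.repeat([0, 1, 2], 4)
X = rng.normal(size=(12, M))
X[:, :40] += 2.0 * y[:, None]

scanner = MultiGrainedScanner(window_lengths=windows, n_trees=5, seed=1)
scan = scanner.fit_transform(X, y)
print("scan vector lengths:", [b.shape[1] for b in scan.per_window])
print("window weights beta:", np.round(scan.beta, 3), "(sum", scan.beta.sum(), ")")

cascade = CascadeForest(n_trees=5, kfold_k=2, fixed_depth=4, seed=2)
cascade.fit(scan, y)
print("cascade layer input dims:", cascade.input_dims_)
print("augmented class vector per layer: 4 forests x 3 classes =", 4 * C)
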