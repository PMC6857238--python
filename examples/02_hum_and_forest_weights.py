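"""Score two classifiers by multi-class HUM and turn that into weights.

HUM (hypervolume under the ROC manifold) generalizes AUC: it is the
probability that one sample drawn from each class is concordantly ranked.
A perfect 3-class scorer reaches 1.0; label-free scores sit near
(1/3)^3 = 0.037.  Normalizing two forests' HUM values gives the alpha
weights applied to their scan vectors.
"""

import numpy as np

from omicforest import binary_auc, forest_weights, hum

rng = np.random.default_rng(0)
n = 200
labels = np.repeat([0, 1, 2], n)

# a good scorer: probability mass leans toward the true class
good = rng.dirichlet([1, 1, 1], size=3 * n)
good[np.arange(3 * n), labels] += 0.5
good /= good.sum(axis=1, keepdims=True)

# an uninformative scorer
chance = rng.dirichlet([1, 1, 1], size=3 * n)

hum_good = hum(good, labels)
hum_chance = hum(chance, labels)
print(f"HUM good scorer:      {hum_good:.3f}")
print(f"HUM chance scorer:    {hum_chance:.3f}  (chance level {(1/3)**3:.3f})")

w = forest_weights(hum_good, hum_chance)
print(f"alpha weights:        ({w.alpha1:.3f}, {w.alpha2:.3f})  -> the good forest dominates")

auc = binary_auc(good[:, 0], (labels == 0).astype(int))
print(f"one-vs-rest AUC (class 0 of the good scorer): {auc:.3f}")
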