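"""Binary AUC, multi-class HUM, and the HUM-derived forest weights.

The hypervolume under the ROC manifold (HUM) generalizes the binary AUC to C
classes: it is the probability that a randomly drawn C-tuple (one sample per
class) is concordantly classified.  We use the argmax-concordance estimator:
a tuple counts as concordant when every member's own-class score is the
maximum of its score row (ties broken toward the lowest class index).
Because the argmax criterion is applied row-by-row, the fraction of
concordant tuples over the full enumeration factorizes exactly into the
product of within-class top-1 accuracies, which is what :func:`hum` computes;
it equals full enumeration at any sample size.  A perfect classifier scores
1, and scores independent of the labels give (1/C)^C in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["binary_auc", "hum", "forest_weights", "ForestWeights"]


def binary_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) with ties counted 1/2.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("binary AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks implement the tie = 1/2 rule
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def hum(prob_matrix, labels) -> float:
    """Exact argmax-concordance HUM of an n x C score matrix.

    Rows need not be normalized; only the row argmax matters.  All C classes
    must be present.  The value equals the full tuple enumeration (product of
    within-class top-1 accuracies), computed in O(nC).
    """
    prob = np.asarray(prob_matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if prob.ndim != 2 or prob.shape[0] != len(labels):
        raise ValueError("prob_matrix must be n x C aligned with labels")
    if not np.isfinite(prob).all():
        raise ValueError("scores must be finite")
    n_classes = prob.shape[1]
    pred = np.argmax(prob, axis=1)  # np.argmax ties -> lowest index
    value = 1.0
    for c in range(n_classes):
        in_c = labels == c
        if not in_c.any():
            raise ValueError(f"class {c} absent; HUM requires every class represented")
        value *= float(np.mean(pred[in_c] == c))
    return value


@dataclass(frozen=True)
class ForestWeights:
    """Normalized pair of forest weights (alpha1 + alpha2 = 1)."""

    alpha1: float
    alpha2: float

    def __post_init__(self):
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("forest weights must be non-negative")
        if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-12:
            raise ValueError("forest weights must sum to 1")


def forest_weights(hum1: float, hum2: float) -> ForestWeights:
    """Normalize the two scanning forests' HUM values into weights.

    ``alpha_i = HUM_i / (HUM_1 + HUM_2)``; both zero degrades to equal
    weights with a warning.
    """
    if hum1 < 0 or hum2 < 0:
        raise ValueError("HUM values must be non-negative")
    total = hum1 + hum2
    if total == 0:
        warnings.warn("both HUM values are zero; falling back to equal forest weights")
        return ForestWeights(0.5, 0.5)
    a1 = hum1 / total
    return ForestWeights(a1, 1.0 - a1)
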