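"""Decision-level fusion of per-modality classifiers by weighted voting.

Each modality contributes its model's C-dim probability output h_p(x); the
fused score for class q is sum_p gamma_p * h_p^q(x) and the prediction is
its argmax (ties to the lowest class index).  The influence weights gamma
are the modality models' validation accuracies normalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["modality_weights", "fuse_proba", "fuse_predict", "FusionModel"]


def modality_weights(accuracies) -> np.ndarray:
    """gamma_p = acc_p / sum_i acc_i over the m modality models."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 1 or acc.size == 0:
        raise ValueError("need a 1-D non-empty accuracy vector")
    if (acc < 0).any():
        raise ValueError("accuracies must be non-negative")
    total = acc.sum()
    if total == 0:
        raise ValueError("all modality accuracies are zero; cannot derive weights")
    return acc / total


def fuse_proba(prob_per_modality, gamma) -> np.ndarray:
    """Convex combination of the m aligned n x C probability matrices."""
    gamma = np.asarray(gamma, dtype=float)
    mats = [np.asarray(p, dtype=float) for p in prob_per_modality]
    if len(mats) != gamma.size:
        raise ValueError("one gamma per modality required")
    shape = mats[0].shape
    for p in mats:
        if p.shape != shape:
            raise ValueError("modality probability matrices must be aligned (same shape)")
    return sum(g * p for g, p in zip(gamma, mats))


def fuse_predict(prob_per_modality, gamma) -> tuple[np.ndarray, np.ndarray]:
    """Fused labels (argmax, ties to lowest class index) and fused scores."""
    fused = fuse_proba(prob_per_modality, gamma)
    return np.argmax(fused, axis=1), fused


@dataclass
class FusionModel:
    """Trained per-modality models plus their normalized influence weights."""

    modality_models: list
    gamma: np.ndarray
    modality_accuracies: np.ndarray
    modalities: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.modality_accuracies = np.asarray(self.modality_accuracies, dtype=float)
        if len(self.modality_models) == 0:
            raise ValueError("need at least one modality model")
        if len(self.modality_models) != self.gamma.size:
            raise ValueError("one gamma per modality model required")
        if (self.gamma < 0).any() or abs(self.gamma.sum() - 1.0) > 1e-12:
            raise ValueError("gamma must be non-negative and sum to 1")

    def predict_proba(self, X_per_modality) -> np.ndarray:
        if len(X_per_modality) != len(self.modality_models):
            raise ValueError("need one aligned input per modality")
        probs = [m.predict_proba(X) for m, X in zip(self.modality_models, X_per_modality)]
        return fuse_proba(probs, self.gamma)

    def predict(self, X_per_modality) -> np.ndarray:
        return np.argmax(self.predict_proba(X_per_modality), axis=1)
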