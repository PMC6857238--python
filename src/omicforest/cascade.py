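"""Cascade forest consuming beta-weighted window vectors layer by layer.

Layer 1 trains on the first (shortest) window's scan vector.  Every later
layer trains on the previous layer's 4*C augmented class vector concatenated
with the next window's scan vector, cycling through the windows in ascending
length order; with windows (100, 200, 300) on a 400-dim input and C = 3
classes this reproduces the layer input sizes 1806 -> 1818 -> 1218 -> 618.

Each layer holds two random forests and two completely random forests.  The
augmented class vectors used for *training* the next layer come from k-fold
cross-fitting within the layer (each sample's vector predicted by forests
that never saw it), which curbs overfitting on small samples.  Growth stops
when validation accuracy fails to beat the running best by more than
``stop_tol`` (patience one layer) and the model is truncated to the best
depth; alternatively ``fixed_depth`` grows an exact number of layers with no
validation requirement.  Prediction averages the last layer's four C-dim
probability vectors and takes the argmax (ties to the lowest class index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

from ._folds import stratified_folds
from ._seeds import derive_seed
from .scanning import ScanOutput, _full_proba

__all__ = ["CascadeLayer", "CascadeForest"]


@dataclass
class CascadeLayer:
    """One cascade level: four trained forests over a fixed input layout."""

    forests: list
    window_idx: int
    input_dim: int


def _layer_forests(n_trees: int, n_classes: int, seed: int) -> list:
    ests = []
    for j in range(2):
        ests.append(
            RandomForestClassifier(
                n_estimators=n_trees, n_jobs=1, random_state=derive_seed(seed, "rf", j)
            )
        )
    for j in range(2):
        ests.append(
            ExtraTreesClassifier(
                n_estimators=n_trees,
                max_features=1,
                n_jobs=1,
                random_state=derive_seed(seed, "crf", j),
            )
        )
    return ests


class CascadeForest:
    """Grow, early-stop and apply the cascade of 4-forest layers.

    Parameters
    ----------
    n_trees
        Trees per cascade forest (four forests per layer).
    kfold_k
        Folds for in-layer cross-fitting of augmented class vectors.
    stop_tol
        Minimum validation-accuracy improvement that counts as a gain.
    max_depth
        Hard cap on grown layers.
    fixed_depth
        Grow exactly this many layers and skip validation-based stopping.
    seed
        Master seed for all layer forests and fold shuffles.
    """

    def __init__(
        self,
        n_trees: int = 300,
        kfold_k: int = 3,
        stop_tol: float = 0.0,
        max_depth: int = 10,
        fixed_depth: int | None = None,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.kfold_k = kfold_k
        self.stop_tol = stop_tol
        self.max_depth = max_depth
        self.fixed_depth = fixed_depth
        self.seed = seed
        self.layers_: list[CascadeLayer] = []
        self.val_scores_: list[float] = []
        self.input_dims_: list[int] = []
        self.best_depth_: int = 0

    # -- internals ---------------------------------------------------------

    def _layer_input(self, scan: ScanOutput, depth: int, aug: np.ndarray | None) -> np.ndarray:
        T = len(scan.per_window)
        if depth == 1:
            return scan.per_window[0]
        widx = (depth - 2) % T
        return np.hstack([aug, scan.per_window[widx]])

    def _crossfit_aug(self, est, X: np.ndarray, y: np.ndarray, n_classes: int, seed: int) -> np.ndarray:
        k = min(self.kfold_k, int(np.min(np.bincount(y))))
        if k < 2:
            warnings.warn("too few samples per class for cross-fitting; using in-sample vectors")
            return _full_proba(est, X, n_classes)
        out = np.zeros((X.shape[0], n_classes))
        for f, (tr, te) in enumerate(stratified_folds(y, k, derive_seed(seed, "fold"))):
            sub = clone(est)
            sub.set_params(random_state=derive_seed(seed, "fold-est", f))
            sub.fit(X[tr], y[tr])
            out[te] = _full_proba(sub, X[te], n_classes)
        return out

    # -- API ---------------------------------------------------------------

    def fit(
        self,
        scan: ScanOutput,
        y,
        scan_val: ScanOutput | None = None,
        y_val=None,
    ) -> "CascadeForest":
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("cascade requires at least two classes")
        if self.fixed_depth is None and (scan_val is None or y_val is None or len(np.asarray(y_val)) == 0):
            raise ValueError("early stopping requires a non-empty validation set (or set fixed_depth)")
        n_classes = scan.n_classes
        self.n_classes_ = n_classes
        self.window_lengths_ = list(scan.window_lengths)
        y_val = None if y_val is None else np.asarray(y_val, dtype=int)

        self.layers_, self.val_scores_, self.input_dims_ = [], [], []
        aug_train = aug_val = None
        best_score, best_depth = -np.inf, 0
        target_depth = self.fixed_depth if self.fixed_depth is not None else self.max_depth

        for depth in range(1, target_depth + 1):
            X_layer = self._layer_input(scan, depth, aug_train)
            seed_d = derive_seed(self.seed, "layer", depth)
            forests = _layer_forests(self.n_trees, n_classes, seed_d)
            aug_blocks, cv_blocks = [], []
            for j, est in enumerate(forests):
                est.fit(X_layer, y)
                cv_blocks.append(
                    self._crossfit_aug(est, X_layer, y, n_classes, derive_seed(seed_d, "cf", j))
                )
            T = len(scan.per_window)
            widx = 0 if depth == 1 else (depth - 2) % T
            self.layers_.append(CascadeLayer(forests, widx, X_layer.shape[1]))
            self.input_dims_.append(X_layer.shape[1])
            aug_train = np.hstack(cv_blocks)

            if scan_val is not None and y_val is not None and len(y_val):
                Xv = self._layer_input(scan_val, depth, aug_val)
                probs = [_full_proba(est, Xv, n_classes) for est in forests]
                aug_val = np.hstack(probs)
                mean_probs = np.mean(probs, axis=0)
                score = float(np.mean(np.argmax(mean_probs, axis=1) == y_val))
                self.val_scores_.append(score)
            else:
                score = None

            if self.fixed_depth is not None:
                best_depth = depth
                continue
            if score > best_score + self.stop_tol:
                best_score, best_depth = score, depth
            else:  # patience 1: first non-improving layer terminates growth
                break

        self.best_depth_ = best_depth
        self.layers_ = self.layers_[:best_depth]
        self.input_dims_ = self.input_dims_[:len(self.layers_)]
        return self

    def predict_proba(self, scan: ScanOutput) -> np.ndarray:
        if not self.layers_:
            raise ValueError("cascade is not fitted")
        if list(scan.window_lengths) != self.window_lengths_:
            raise ValueError("scan windows do not match the fitted cascade")
        aug = None
        for depth, layer in enumerate(self.layers_, start=1):
            X_layer = self._layer_input(scan, depth, aug)
            if X_layer.shape[1] != layer.input_dim:
                raise ValueError(
                    f"layer {depth} input dim {X_layer.shape[1]} != trained {layer.input_dim}"
                )
            probs = [_full_proba(est, X_layer, self.n_classes_) for est in layer.forests]
            aug = np.hstack(probs)
        final = np.mean(probs, axis=0)
        return final / final.sum(axis=1, keepdims=True)

    def predict(self, scan: ScanOutput) -> np.ndarray:
        return np.argmax(self.predict_proba(scan), axis=1)
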