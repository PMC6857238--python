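"""The per-modality weighted deep forest: selection -> scanning -> cascade.

``WeightedDeepForest`` wires the optional lasso selection, the HUM/ability
weighted multi-grained scanner and the cascade forest into one estimator
with the familiar fit / predict_proba / predict surface.  Early stopping
needs a validation split (pass ``X_val``/``y_val``) unless ``fixed_depth``
pins the cascade depth.
"""

from __future__ import annotations

import numpy as np

from ._seeds import derive_seed
from .cascade import CascadeForest
from .containers import FeatureMatrix, LabelVector
from .feature_selection import LassoSpec, lasso_select
from .scanning import MultiGrainedScanner

__all__ = ["WeightedDeepForest"]


class WeightedDeepForest:
    """One modality's multi-weighted gcForest-style classifier.

    Parameters
    ----------
    windows, stride, n_trees_scan
        Scanner configuration (windows default to ~M/4, M/2, 3M/4).
    n_trees_cascade, kfold_k, stop_tol, max_depth, fixed_depth
        Cascade configuration.
    select_target
        Lasso-select this many features before scanning (skipped when the
        table has at most ``select_skip_below`` columns, the CNV-style case).
    force_alpha, force_uniform_beta
        Disable the HUM / sorting-optimization weighting (for comparisons
        against the standard unweighted scanner).
    """

    def __init__(
        self,
        windows: list[int] | None = None,
        stride: int = 1,
        n_trees_scan: int = 300,
        n_trees_cascade: int = 300,
        kfold_k: int = 3,
        stop_tol: float = 0.0,
        max_depth: int = 10,
        fixed_depth: int | None = None,
        select_target: int | None = None,
        select_skip_below: int = 50,
        force_alpha: tuple[float, float] | None = None,
        force_uniform_beta: bool = False,
        seed: int = 0,
    ):
        self.windows = windows
        self.stride = stride
        self.n_trees_scan = n_trees_scan
        self.n_trees_cascade = n_trees_cascade
        self.kfold_k = kfold_k
        self.stop_tol = stop_tol
        self.max_depth = max_depth
        self.fixed_depth = fixed_depth
        self.select_target = select_target
        self.select_skip_below = select_skip_below
        self.force_alpha = force_alpha
        self.force_uniform_beta = force_uniform_beta
        self.seed = seed

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            return X.values
        return np.asarray(X, dtype=float)

    @staticmethod
    def _labels(y) -> np.ndarray:
        if isinstance(y, LabelVector):
            return y.labels
        return np.asarray(y, dtype=int)

    def fit(self, X, y, X_val=None, y_val=None) -> "WeightedDeepForest":
        Xm, ym = self._matrix(X), self._labels(y)
        self.selected_: np.ndarray | None = None
        if self.select_target is not None and Xm.shape[1] > self.select_skip_below:
            fm = X if isinstance(X, FeatureMatrix) else FeatureMatrix(
                [f"s{i}" for i in range(Xm.shape[0])],
                Xm,
                [f"f{j}" for j in range(Xm.shape[1])],
            )
            lv = y if isinstance(y, LabelVector) else LabelVector(
                fm.sample_ids, ym, [str(c) for c in range(int(ym.max()) + 1)]
            )
            res = lasso_select(
                fm, lv, LassoSpec(target_count=min(self.select_target, Xm.shape[1]),
                                  seed=derive_seed(self.seed, "lasso"))
            )
            self.selected_ = res.selected_indices
            Xm = Xm[:, self.selected_]

        self.scanner_ = MultiGrainedScanner(
            window_lengths=self.windows,
            stride=self.stride,
            n_trees=self.n_trees_scan,
            seed=derive_seed(self.seed, "scan"),
            force_alpha=self.force_alpha,
            force_uniform_beta=self.force_uniform_beta,
        )
        scan_train = self.scanner_.fit_transform(Xm, ym)
        scan_val = yv = None
        if X_val is not None and y_val is not None:
            Xv = self._matrix(X_val)
            if self.selected_ is not None:
                Xv = Xv[:, self.selected_]
            scan_val = self.scanner_.transform(Xv)
            yv = self._labels(y_val)
        self.cascade_ = CascadeForest(
            n_trees=self.n_trees_cascade,
            kfold_k=self.kfold_k,
            stop_tol=self.stop_tol,
            max_depth=self.max_depth,
            fixed_depth=self.fixed_depth,
            seed=derive_seed(self.seed, "cascade"),
        )
        self.cascade_.fit(scan_train, ym, scan_val, yv)
        return self

    def _scan(self, X):
        Xm = self._matrix(X)
        if self.selected_ is not None:
            Xm = Xm[:, self.selected_]
        return self.scanner_.transform(Xm)

    def predict_proba(self, X) -> np.ndarray:
        return self.cascade_.predict_proba(self._scan(X))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
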