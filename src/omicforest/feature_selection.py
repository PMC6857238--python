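"""Embedded L1 (lasso) feature selection to a budget or an exact count.

Two ways to specify the selection:

* ``z`` — the lasso budget: minimize squared error subject to
  sum_j |delta_j| <= z.  Solved through the penalized form by bisecting the
  penalty until the coefficient L1 norm meets the budget; z -> infinity
  selects everything, z = 0 compresses every coefficient to zero (an error,
  since nothing survives).
* ``target_count`` — the exact number of features to retain (the workflow
  used for omics tables where a fixed column count is wanted).  For
  multinomial labels the default loss is one-vs-rest L1-penalized logistic
  regression, the selected set being the union of nonzero coefficients
  across classes; the penalty strength is bisected until the count lands
  within +/-2 of the target, then the set is trimmed/extended by coefficient
  magnitude to hit it exactly.  ``loss="squared"`` treats the class codes as
  a numeric response and uses the plain lasso instead.

Tables with very few columns (CNV-style) are typically not selected at all;
pipelines skip selection when M is at or below a small threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

from .containers import FeatureMatrix, LabelVector

__all__ = ["LassoSpec", "SelectionResult", "lasso_select"]


@dataclass
class LassoSpec:
    """How to run the selection; exactly one of ``z`` / ``target_count`` is set."""

    z: float | None = None
    target_count: int | None = None
    standardize: bool = True
    loss: str = "logistic"  # "logistic" (one-vs-rest) or "squared" (class codes)
    seed: int = 0
    max_bisect: int = 50

    def __post_init__(self):
        if (self.z is None) == (self.target_count is None):
            raise ValueError("set exactly one of z and target_count")
        if self.loss not in ("logistic", "squared"):
            raise ValueError("loss must be 'logistic' or 'squared'")


@dataclass
class SelectionResult:
    """Selected feature indices (sorted, unique) plus the fitted coefficients."""

    selected_indices: np.ndarray
    coefficients: np.ndarray  # (n_classes or 1) x M
    achieved_count: int
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        assert self.achieved_count == len(self.selected_indices)


_NONZERO = 1e-10


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all features are constant; nothing to select")
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def _fit_coefs(X: np.ndarray, y: np.ndarray, spec: LassoSpec, strength: float) -> np.ndarray:
    """Coefficient matrix at a given penalty strength (higher => sparser)."""
    if spec.loss == "squared":
        est = Lasso(alpha=strength, max_iter=20000, tol=1e-8, random_state=spec.seed)
        est.fit(X, y.astype(float))
        return est.coef_[None, :]
    base = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=1.0 / strength,
        solver="liblinear",
        tol=1e-8,
        max_iter=5000,
        random_state=spec.seed,
    )
    est = OneVsRestClassifier(base)
    est.fit(X, y)
    return np.vstack([e.coef_ for e in est.estimators_])


def _count(coefs: np.ndarray) -> int:
    return int((np.abs(coefs) > _NONZERO).any(axis=0).sum())


def _select_by_budget(X, y, spec: LassoSpec) -> np.ndarray:
    if spec.z == 0:
        raise ValueError("z = 0 compresses every coefficient to zero; no features selected")
    lo, hi = 1e-6, 1e4  # penalty bracket; hi kills everything, lo keeps all
    coefs = _fit_coefs(X, y, spec, lo)
    if np.abs(coefs).sum() <= spec.z:
        return coefs  # budget not binding: effectively unconstrained
    for _ in range(spec.max_bisect):
        mid = np.sqrt(lo * hi)
        coefs = _fit_coefs(X, y, spec, mid)
        if np.abs(coefs).sum() > spec.z:
            lo = mid
        else:
            hi = mid
    return _fit_coefs(X, y, spec, hi)


def _select_by_count(X, y, spec: LassoSpec):
    M = X.shape[1]
    target = spec.target_count
    lo, hi = 1e-6, 1e4
    best = None  # (distance to band, count, strength, coefs)
    for _ in range(spec.max_bisect):
        mid = np.sqrt(lo * hi)
        coefs = _fit_coefs(X, y, spec, mid)
        cnt = _count(coefs)
        dist = max(0, abs(cnt - target) - 2)
        if best is None or dist < best[0]:
            best = (dist, cnt, mid, coefs)
        if dist == 0:
            break
        if cnt > target:
            lo = mid  # too many survivors: strengthen penalty
        else:
            hi = mid
    if best is None or best[0] > 0:
        raise RuntimeError(
            f"penalty bisection did not reach within 2 of target_count={target} "
            f"after {spec.max_bisect} steps (closest count {None if best is None else best[1]})"
        )
    _, cnt, strength, coefs = best
    magnitude = np.abs(coefs).max(axis=0)
    selected = magnitude > _NONZERO
    if cnt != target:
        # reference fit at a weak penalty ranks the features the penalty zeroed
        ref_mag = np.abs(_fit_coefs(X, y, spec, lo)).max(axis=0)
        order = np.lexsort((np.arange(M), -ref_mag, -selected.astype(int), -magnitude * selected))
        keep = np.zeros(M, dtype=bool)
        keep[order[:target]] = True
        selected = keep
    return selected, coefs


def lasso_select(fm: FeatureMatrix, lv: LabelVector, spec: LassoSpec) -> SelectionResult:
    """Run the selection on one modality's feature matrix."""
    X = np.asarray(fm.values, dtype=float)
    y = np.asarray(lv.labels, dtype=int)
    n, M = X.shape
    if n < lv.n_classes:
        raise ValueError("need at least as many samples as classes")
    if spec.target_count is not None and spec.target_count > M:
        raise ValueError(f"target_count {spec.target_count} exceeds M={M}")
    if spec.standardize:
        X = _standardize(X)
    elif np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant; nothing to select")

    if spec.z is not None:
        coefs = _select_by_budget(X, y, spec)
        selected = (np.abs(coefs) > _NONZERO).any(axis=0)
        if not selected.any():
            raise ValueError("budget too tight: zero features selected")
    else:
        selected, coefs = _select_by_count(X, y, spec)

    idx = np.flatnonzero(selected)
    return SelectionResult(
        selected_indices=idx,
        coefficients=coefs,
        achieved_count=len(idx),
        feature_names=[fm.feature_names[i] for i in idx],
    )
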