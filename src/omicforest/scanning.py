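"""Multi-grained scanning with HUM-weighted forests and window weights.

A raw M-dimensional feature vector is cut into V = floor((M - L)/S) + 1
overlapping windows of length L.  Every window instance (inheriting its
parent sample's label) trains one random forest and one completely random
forest; each sample's window-level class-probability outputs are
concatenated into a 2*V*C vector in which the random-forest half is scaled
by alpha1 and the completely-random half by alpha2, the weights obtained by
normalizing the two forests' out-of-bag HUM values.

Window (granularity) weights beta come from the sorting-optimization
statistic: for each sample the mean of the top 1/C fraction of its sorted
class vector approximates how confidently this window predicts the sample;
averaging over samples gives the window's ability, and normalizing the
abilities over windows gives beta.  ``transform`` emits, per window, the
beta-scaled class vectors that the cascade consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

from ._seeds import derive_seed
from .hum import ForestWeights, forest_weights, hum

__all__ = [
    "WindowSpec",
    "ForestPair",
    "ScanOutput",
    "window_count",
    "scan",
    "default_window_lengths",
    "fit_window",
    "window_class_vectors",
    "t_ability",
    "window_weights",
    "MultiGrainedScanner",
]


def window_count(M: int, L: int, S: int = 1) -> int:
    """Number of window positions: V = floor((M - L)/S) + 1."""
    if L < 1 or L > M:
        raise ValueError(f"window length {L} must satisfy 1 <= L <= M={M}")
    if S < 1:
        raise ValueError("stride must be >= 1")
    return (M - L) // S + 1


@dataclass(frozen=True)
class WindowSpec:
    """One sliding-window granularity: length L and stride S."""

    length: int
    stride: int = 1

    def count(self, M: int) -> int:
        return window_count(M, self.length, self.stride)


def scan(row, w: WindowSpec) -> np.ndarray:
    """Cut one M-dim row into its V windows of length L (V x L array)."""
    row = np.asarray(row, dtype=float)
    if row.ndim != 1:
        raise ValueError("scan expects a single 1-D feature vector")
    V = w.count(row.shape[0])
    return np.stack([row[k * w.stride : k * w.stride + w.length] for k in range(V)])


def _window_instances(X: np.ndarray, w: WindowSpec) -> np.ndarray:
    """All windows of all samples, shape (n, V, L)."""
    n, M = X.shape
    V = w.count(M)
    sw = np.lib.stride_tricks.sliding_window_view(X, w.length, axis=1)
    return np.ascontiguousarray(sw[:, :: w.stride, :][:, :V, :])


def default_window_lengths(M: int) -> list[int]:
    """Three granularities at roughly 1/4, 1/2 and 3/4 of the feature size.

    Gives (100, 200, 300) for M = 400; degenerate sizes are deduplicated.
    """
    lengths = []
    for frac in (0.25, 0.5, 0.75):
        L = min(M, max(1, math.ceil(frac * M)))
        if L not in lengths:
            lengths.append(L)
    return lengths


@dataclass
class ForestPair:
    """A (random forest, completely random forest) pair for one window."""

    rf: RandomForestClassifier
    crf: ExtraTreesClassifier
    spec: WindowSpec
    n_classes: int
    weights: ForestWeights
    oob_hum: tuple[float, float]


def _oob_probs(est, n_classes: int) -> np.ndarray:
    """Out-of-bag class probabilities, NaN rows replaced by uniform."""
    probs = np.array(est.oob_decision_function_, dtype=float)
    bad = ~np.isfinite(probs).all(axis=1)
    if bad.any():
        probs[bad] = 1.0 / n_classes
    full = np.full((probs.shape[0], n_classes), 0.0)
    for j, c in enumerate(est.classes_.astype(int)):
        full[:, c] = probs[:, j]
    return full


def fit_window(X, y, w: WindowSpec, n_trees: int = 300, seed: int = 0) -> ForestPair:
    """Train the forest pair on all window instances and weight it by OOB HUM.

    Window instances inherit their parent sample's label.  HUM1/HUM2 are
    measured on each forest's out-of-bag probability estimates over the
    instances, then normalized into (alpha1, alpha2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("window fitting requires at least two classes")
    n_classes = int(classes.max()) + 1
    inst = _window_instances(X, w)
    n, V, L = inst.shape
    Xw = inst.reshape(n * V, L)
    yw = np.repeat(y, V)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        n_jobs=1,
        random_state=derive_seed(seed, "rf", w.length, w.stride),
    )
    crf = ExtraTreesClassifier(
        n_estimators=n_trees,
        max_features=1,
        bootstrap=True,
        oob_score=True,
        n_jobs=1,
        random_state=derive_seed(seed, "crf", w.length, w.stride),
    )
    with warnings.catch_warnings():
        # few trees can leave some instances with no OOB vote; handled below
        warnings.filterwarnings("ignore", message=".*OOB.*")
        rf.fit(Xw, yw)
        crf.fit(Xw, yw)
    hum1 = hum(_oob_probs(rf, n_classes), yw)
    hum2 = hum(_oob_probs(crf, n_classes), yw)
    return ForestPair(rf, crf, w, n_classes, forest_weights(hum1, hum2), (hum1, hum2))


def _full_proba(est, Xw: np.ndarray, n_classes: int) -> np.ndarray:
    probs = est.predict_proba(Xw)
    full = np.zeros((Xw.shape[0], n_classes))
    for j, c in enumerate(est.classes_.astype(int)):
        full[:, c] = probs[:, j]
    return full


def window_class_vectors(X, fp: ForestPair) -> np.ndarray:
    """Alpha-weighted scan vectors, shape (n, 2*V*C).

    concat(RF-vec * alpha1, cRF-vec * alpha2) where RF-vec chains the V
    per-window C-dim probability vectors of the random forest.
    """
    X = np.asarray(X, dtype=float)
    inst = _window_instances(X, fp.spec)
    n, V, L = inst.shape
    Xw = inst.reshape(n * V, L)
    rf_vec = _full_proba(fp.rf, Xw, fp.n_classes).reshape(n, V * fp.n_classes)
    crf_vec = _full_proba(fp.crf, Xw, fp.n_classes).reshape(n, V * fp.n_classes)
    return np.hstack([rf_vec * fp.weights.alpha1, crf_vec * fp.weights.alpha2])


def t_ability(v, C: int) -> float:
    """Mean of the top 1/C fraction of the descending-sorted class vector."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty class vector")
    k = max(1, v.size // C)
    top = np.partition(v, v.size - k)[v.size - k :]
    return float(top.mean())


def window_weights(abilities) -> np.ndarray:
    """Normalize per-window abilities into beta weights summing to 1."""
    a = np.asarray(abilities, dtype=float)
    if (a < 0).any():
        raise ValueError("window abilities must be non-negative")
    total = a.sum()
    if total == 0:
        warnings.warn("all window abilities zero; using uniform window weights")
        return np.full(a.shape, 1.0 / a.size)
    return a / total


@dataclass
class ScanOutput:
    """Beta-scaled per-window class vectors for a set of samples."""

    per_window: list[np.ndarray]  # each (n, 2*V_t*C)
    beta: np.ndarray
    window_lengths: list[int]
    n_classes: int

    @property
    def n_samples(self) -> int:
        return self.per_window[0].shape[0]


class MultiGrainedScanner:
    """Fits the per-window forest pairs and the alpha/beta weighting.

    Parameters
    ----------
    window_lengths
        Window sizes; default picks ~M/4, M/2, 3M/4 at fit time.
    stride
        Scan stride S (default 1).
    n_trees
        Trees per scanning forest.
    seed
        Master seed; all internal randomness derives from it.
    force_alpha
        Optional (a1, a2) overriding the HUM-derived forest weights,
        e.g. (0.5, 0.5) to recover standard unweighted scanning.
    force_uniform_beta
        Use uniform window weights instead of the sorting-optimization
        statistic.
    """

    def __init__(
        self,
        window_lengths: list[int] | None = None,
        stride: int = 1,
        n_trees: int = 300,
        seed: int = 0,
        force_alpha: tuple[float, float] | None = None,
        force_uniform_beta: bool = False,
    ):
        self.window_lengths = window_lengths
        self.stride = stride
        self.n_trees = n_trees
        self.seed = seed
        self.force_alpha = force_alpha
        self.force_uniform_beta = force_uniform_beta
        self.forest_pairs_: list[ForestPair] = []
        self.beta_: np.ndarray | None = None
        self.abilities_: np.ndarray | None = None

    def fit(self, X, y) -> "MultiGrainedScanner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        M = X.shape[1]
        lengths = self.window_lengths or default_window_lengths(M)
        self.lengths_ = sorted(lengths)
        self.n_classes_ = int(np.max(y)) + 1
        self.forest_pairs_ = []
        abilities = []
        self._fit_vectors_ = []  # cache so fit_transform need not re-predict
        for t, L in enumerate(self.lengths_):
            w = WindowSpec(L, self.stride)
            fp = fit_window(X, y, w, self.n_trees, derive_seed(self.seed, "window", t))
            if self.force_alpha is not None:
                fp.weights = ForestWeights(*self.force_alpha)
            self.forest_pairs_.append(fp)
            vecs = window_class_vectors(X, fp)
            self._fit_vectors_.append(vecs)
            abilities.append(
                float(np.mean([t_ability(v, self.n_classes_) for v in vecs]))
            )
        self.abilities_ = np.asarray(abilities)
        if self.force_uniform_beta:
            self.beta_ = np.full(len(self.lengths_), 1.0 / len(self.lengths_))
        else:
            self.beta_ = window_weights(self.abilities_)
        return self

    def transform(self, X) -> ScanOutput:
        if self.beta_ is None:
            raise ValueError("scanner is not fitted")
        X = np.asarray(X, dtype=float)
        per_window = [
            self.beta_[t] * window_class_vectors(X, fp)
            for t, fp in enumerate(self.forest_pairs_)
        ]
        return ScanOutput(per_window, self.beta_.copy(), list(self.lengths_), self.n_classes_)

    def fit_transform(self, X, y) -> ScanOutput:
        self.fit(X, y)
        per_window = [self.beta_[t] * v for t, v in enumerate(self._fit_vectors_)]
        self._fit_vectors_ = []  # free memory; cache is single-use
        return ScanOutput(per_window, self.beta_.copy(), list(self.lengths_), self.n_classes_)
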