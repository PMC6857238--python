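"""Stratified fold assignment tolerant of very small classes.

Members of each class are shuffled and dealt round-robin across folds, so
every fold's class proportions match the global proportions to within one
sample, and classes smaller than the fold count still land somewhere
(with a warning) instead of failing.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["stratified_folds"]


def stratified_folds(y, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return k (train_idx, test_idx) pairs, stratified by class."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(y):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    offset = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < k:
            warnings.warn(
                f"class {c} has {idx.size} < {k} members; folds round-robin it"
            )
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size  # stagger so small classes spread over different folds
    folds = []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        folds.append((train, test))
    return folds
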