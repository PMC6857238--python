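"""Core in-memory containers: per-modality feature tables and label vectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "LabelVector"]


@dataclass
class FeatureMatrix:
    """One modality's complete samples x features numeric table.

    Invariants (checked on construction): no missing values, unique sample
    ids, unique feature names, at least one sample and one feature.
    """

    sample_ids: list[str]
    values: np.ndarray
    feature_names: list[str]
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("feature matrix must have at least one sample and one feature")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match number of columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_names)) != m:
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str = "") -> "FeatureMatrix":
        return cls(
            sample_ids=list(df.index.astype(str)),
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns.astype(str)),
            modality=modality,
        )

    def subset_samples(self, ids: list[str]) -> "FeatureMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return FeatureMatrix(list(ids), self.values[idx], list(self.feature_names), self.modality)

    def subset_features(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            list(self.sample_ids),
            self.values[:, indices],
            [self.feature_names[i] for i in indices],
            self.modality,
        )


@dataclass
class LabelVector:
    """Integer class codes in {0..C-1} paired with sample ids.

    ``class_names[k]`` is the original label string for code ``k``.
    """

    sample_ids: list[str]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in labels")
        if not self.class_names:
            self.class_names = [str(c) for c in sorted(set(self.labels.tolist()))]
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("label codes outside {0..C-1}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, ids: list[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return LabelVector(list(ids), self.labels[idx], list(self.class_names))
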