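"""Reading and writing feature tables, labels, and persisted models.

Loading applies the column-level missing-data policy used for TCGA-style
exports: columns missing more than ``max_missing_fraction`` of their values
are dropped first, and any column that still contains a missing value after
that is dropped as well, so a loaded :class:`FeatureMatrix` is always
complete.  Samples are never imputed; they are only dropped by multi-modal
alignment (:func:`align`).
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd

from .containers import FeatureMatrix, LabelVector

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "align",
    "save_model",
    "load_model",
]

#: Tokens treated as missing, compared case-insensitively after stripping.
NA_TOKENS = {"", "na", "nan", "null"}


def _read_table(path: str, delimiter: str | None) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            index_col=0,
            dtype=str,
            keep_default_na=False,
        )
    except (OSError, csv.Error, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"could not read table {path!r}: {exc}") from exc


def _to_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    cells = df.apply(lambda col: col.str.strip())
    mask_na = cells.apply(lambda col: col.str.lower().isin(NA_TOKENS))
    out = {}
    for col in cells.columns:
        raw = cells[col].where(~mask_na[col], other=np.nan)
        try:
            out[col] = pd.to_numeric(raw, errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"non-numeric cell in column {col!r} of {path!r} "
                "that is not a recognized NA token"
            ) from exc
    return pd.DataFrame(out, index=df.index)


def read_feature_matrix(
    path: str,
    modality: str = "",
    max_missing_fraction: float = 0.5,
    delimiter: str | None = None,
) -> FeatureMatrix:
    """Load a delimited samples x features table and filter incomplete columns.

    Parameters
    ----------
    path
        Delimited text file; header row, first column sample ids.  Delimiter
        is sniffed when not given.
    modality
        Free-text tag stored on the returned matrix.
    max_missing_fraction
        Columns with a larger fraction of missing cells are dropped; any
        column still containing a missing value afterwards is also dropped.
    """
    df = _read_table(path, delimiter)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path!r}: {dupes}")
    num = _to_numeric(df, path)
    frac_missing = num.isna().mean(axis=0)
    num = num.loc[:, frac_missing <= max_missing_fraction]
    num = num.loc[:, num.notna().all(axis=0)]  # any-null rule
    if num.shape[1] == 0:
        raise ValueError(f"no complete columns survive missing-data filtering in {path!r}")
    return FeatureMatrix.from_frame(num, modality=modality)


def _atomic_write_text(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_feature_matrix(fm: FeatureMatrix, path: str, delimiter: str = ",") -> None:
    """Write a feature matrix as delimited text (full float precision)."""
    text = fm.to_frame().to_csv(sep=delimiter, float_format="%.17g")
    _atomic_write_text(path, text)


def read_labels(
    path: str,
    class_order: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> LabelVector:
    """Load a two-column (sample id, label) file into integer class codes.

    Codes follow ``class_order`` when given, else the lexicographic order of
    the observed label strings; the mapping is recorded in ``class_names``.
    """
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            dtype=str,
            keep_default_na=False,
        )
    except (OSError, csv.Error, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"could not read labels {path!r}: {exc}") from exc
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"labels file {path!r} must have >=1 row and 2 columns")
    ids = df.iloc[:, 0].str.strip().tolist()
    raw = df.iloc[:, 1].str.strip().tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in labels file {path!r}")
    if class_order is None:
        names = sorted(set(raw))
    else:
        names = [str(c) for c in class_order]
        unknown = sorted(set(raw) - set(names))
        if unknown:
            raise ValueError(f"labels {unknown} not present in class_order")
    code = {c: k for k, c in enumerate(names)}
    return LabelVector(ids, np.array([code[r] for r in raw]), names)


def write_labels(lv: LabelVector, path: str, delimiter: str = ",") -> None:
    rows = [f"sample_id{delimiter}label"]
    rows += [
        f"{s}{delimiter}{lv.class_names[c]}" for s, c in zip(lv.sample_ids, lv.labels)
    ]
    _atomic_write_text(path, "\n".join(rows) + "\n")


def align(
    fms: Iterable[FeatureMatrix], lv: LabelVector
) -> tuple[list[FeatureMatrix], LabelVector]:
    """Restrict all modalities and labels to their common samples.

    Samples lacking any modality (or a label) are dropped; all outputs share
    the same row order, which follows the label vector's order.
    """
    fms = list(fms)
    if not fms:
        raise ValueError("need at least one feature matrix")
    common = set(lv.sample_ids)
    for fm in fms:
        common &= set(fm.sample_ids)
    if not common:
        raise ValueError("no samples shared across all modalities and labels")
    ids = [s for s in lv.sample_ids if s in common]
    return [fm.subset_samples(ids) for fm in fms], lv.subset(ids)


def save_model(obj, path: str, manifest: dict) -> None:
    """Persist a trained model as a joblib archive with a JSON manifest."""
    payload = {"manifest": dict(manifest), "payload": obj}
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        joblib.dump(payload, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def load_model(path: str) -> tuple[object, dict]:
    try:
        payload = joblib.load(path)
    except OSError as exc:
        raise ValueError(f"could not read model archive {path!r}: {exc}") from exc
    return payload["payload"], payload["manifest"]


def manifest_json(manifest: dict) -> str:
    return json.dumps(manifest, sort_keys=True, indent=2)
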