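"""Nested cross-validation and multi-class metrics.

The outer loop gives the error estimate: each outer training set is handed
to an inner loop that (per modality) refits feature selection, fits the
scanner and cascade with early stopping on the inner validation fold, and
records the validation accuracy.  The inner results fix the cascade depth
(median of the inner best depths) and yield acc_mp, the per-modality
accuracy that is normalized into the fusion weights gamma; the per-modality
models are then refit on the full outer training set at that depth and
fused once on the outer test fold.  No outer-test sample ever enters an
inner fit (asserted by id bookkeeping).

Precision/recall/F1 are macro-averaged (the cohorts this targets are
imbalanced, and macro averaging keeps the small late-stage class visible);
AUC is the unweighted mean of one-vs-rest binary AUCs, reported alongside
the C-class HUM.
"""

from __future__ import annotations

import warnings
from statistics import median

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from ._folds import stratified_folds
from ._seeds import derive_seed
from .containers import FeatureMatrix, LabelVector
from .fusion import fuse_predict, modality_weights
from .hum import binary_auc, hum
from .model import WeightedDeepForest

__all__ = ["compute_metrics", "nested_cv", "plot_roc"]

_METRIC_KEYS = ("accuracy", "precision", "recall", "f1", "auc", "hum")


def compute_metrics(y_true, y_pred, prob_matrix=None) -> dict:
    """Accuracy, macro precision/recall/F1, macro one-vs-rest AUC, HUM."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    out = {"accuracy": float(np.mean(y_true == y_pred))}
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0
    )
    out.update(precision=float(prec), recall=float(rec), f1=float(f1))
    out["auc"] = np.nan
    out["hum"] = np.nan
    if prob_matrix is not None:
        prob = np.asarray(prob_matrix, dtype=float)
        if prob.shape[0] != len(y_true):
            raise ValueError("prob_matrix not aligned with y_true")
        aucs = []
        for c in range(prob.shape[1]):
            binary = (y_true == c).astype(int)
            if 0 < binary.sum() < len(binary):
                aucs.append(binary_auc(prob[:, c], binary))
        if aucs:
            out["auc"] = float(np.mean(aucs))
        present = {int(c) for c in np.unique(y_true)}
        if present == set(range(prob.shape[1])):
            out["hum"] = hum(prob, y_true)
    return out


def _fit_modality(
    fm: FeatureMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    inner_k: int,
    params: dict,
    select_target: int | None,
    seed: int,
) -> tuple[WeightedDeepForest, float]:
    """Inner CV on one outer-train set -> (refit model, inner accuracy)."""
    X = fm.values
    y_tr = y[train_idx]
    accs, depths = [], []
    for f, (itr, ival) in enumerate(stratified_folds(y_tr, inner_k, derive_seed(seed, "inner"))):
        model = WeightedDeepForest(
            **params, select_target=select_target, seed=derive_seed(seed, "inner-fit", f)
        )
        model.fit(X[train_idx][itr], y_tr[itr], X[train_idx][ival], y_tr[ival])
        accs.append(float(np.mean(model.predict(X[train_idx][ival]) == y_tr[ival])))
        depths.append(model.cascade_.best_depth_)
    depth = max(1, int(round(median(depths))))
    final = WeightedDeepForest(
        **{**params, "fixed_depth": depth},
        select_target=select_target,
        seed=derive_seed(seed, "refit"),
    )
    final.fit(X[train_idx], y_tr)
    return final, float(np.mean(accs))


def nested_cv(
    fms: dict[str, FeatureMatrix],
    lv: LabelVector,
    outer_k: int = 10,
    inner_k: int = 10,
    seed: int = 0,
    model_params: dict | None = None,
    select_targets: dict | None = None,
) -> dict:
    """Run the full nested-CV evaluation of the fused multi-modal model.

    ``model_params`` are forwarded to every :class:`WeightedDeepForest`
    (tree counts, windows, stop_tol, ...); ``select_targets`` maps modality
    name to a lasso target count (omitted modalities skip selection).
    """
    if outer_k < 2:
        raise ValueError("outer_k must be >= 2")
    y = lv.labels
    counts = np.bincount(y, minlength=lv.n_classes)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members")
    params = dict(model_params or {})
    for managed in ("seed", "select_target", "fixed_depth"):
        params.pop(managed, None)  # owned by the CV orchestration
    select_targets = dict(select_targets or {})
    modalities = list(fms)
    all_ids = np.array(lv.sample_ids)

    per_fold = []
    pooled_true, pooled_prob = [], []
    for f, (tr, te) in enumerate(stratified_folds(y, outer_k, derive_seed(seed, "outer"))):
        assert not set(all_ids[tr]) & set(all_ids[te]), "outer train/test overlap"
        fold_probs, inner_accs, test_accs = [], {}, {}
        for modality in modalities:
            model, acc = _fit_modality(
                fms[modality], y, tr, inner_k, params,
                select_targets.get(modality),
                derive_seed(seed, "fold", f, modality),
            )
            probs = model.predict_proba(fms[modality].values[te])
            fold_probs.append(probs)
            inner_accs[modality] = acc
            test_accs[modality] = float(np.mean(np.argmax(probs, axis=1) == y[te]))
        gamma = modality_weights([inner_accs[m] for m in modalities])
        y_hat, fused = fuse_predict(fold_probs, gamma)
        record = compute_metrics(y[te], y_hat, fused)
        record.update(
            fold=f,
            n_test=int(len(te)),
            gamma={m: float(g) for m, g in zip(modalities, gamma)},
            modality_inner_accuracy=inner_accs,
            modality_test_accuracy=test_accs,
            test_ids=[str(s) for s in all_ids[te]],
        )
        per_fold.append(record)
        pooled_true.extend(int(c) for c in y[te])
        pooled_prob.extend(fused.tolist())

    def _agg(key):
        vals = np.array([r[key] for r in per_fold], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=0))

    report = {
        "outer_k": outer_k,
        "inner_k": inner_k,
        "seed": seed,
        "config": {"model_params": params, "select_targets": select_targets,
                   "modalities": modalities},
        "per_fold": per_fold,
        "mean": {}, "sd": {},
        "modality_mean_accuracy": {
            m: float(np.mean([r["modality_test_accuracy"][m] for r in per_fold]))
            for m in modalities
        },
        "pooled": {"y_true": pooled_true, "prob": pooled_prob},
    }
    for key in _METRIC_KEYS:
        report["mean"][key], report["sd"][key] = _agg(key)
    covered = sorted(s for r in per_fold for s in r["test_ids"])
    assert covered == sorted(lv.sample_ids), "outer folds must partition the cohort"
    return report


def plot_roc(prob_matrix, y_true, path: str, class_names=None) -> None:
    """One-vs-rest ROC curves for each class, written as PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    prob = np.asarray(prob_matrix, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in range(prob.shape[1]):
        binary = (y_true == c).astype(int)
        if binary.sum() in (0, len(binary)):
            continue
        fpr, tpr, _ = roc_curve(binary, prob[:, c])
        name = class_names[c] if class_names else f"class {c}"
        ax.plot(fpr, tpr, label=f"{name} (AUC={binary_auc(prob[:, c], binary):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
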