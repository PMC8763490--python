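"""Stratified k-fold cross-validation and the reporting metric set.

Metrics follow the usual confusion-table definitions, reported as
percentages: accuracy = correct/total; per-class one-vs-rest sensitivity
(= recall) = TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP),
false-positive rate = FP/(FP+TN).  Multiclass values are macro-averaged
(unweighted over classes) by default; micro-averaging is available.  AUC is
the rank-based (Mann–Whitney) area under the ROC curve with midrank tie
handling, macro one-vs-rest for multiclass scores.

A class whose denominator is zero (e.g. precision of a never-predicted
class) is excluded from the macro average with a warning, never silently
counted as 0.

:func:`cross_validate` trains one classifier per fold (15 epochs per fold by
default, so a 10-fold run accounts exactly 150 training epochs), evaluates on
the held-out fold and emits per-fold rows plus their arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "stratified_kfold",
    "confusion_metrics",
    "auc",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    """Fold index (1..k) per sample plus the stratification labels."""

    fold: np.ndarray
    labels: np.ndarray
    k: int
    modality: np.ndarray | None = None  # optional per-fold bookkeeping tag

    def split(self, fold_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, validation_indices) for one round."""
        if not 1 <= fold_index <= self.k:
            raise ValueError(f"fold_index must be in 1..{self.k}")
        val = np.nonzero(self.fold == fold_index)[0]
        trn = np.nonzero(self.fold != fold_index)[0]
        return trn, val


@dataclass
class MetricsReport:
    """Per-fold metric rows plus their mean, Table-style."""

    frame: "object"  # pandas DataFrame: rows fold 1..k + "Mean value"
    histories: list = field(default_factory=list)
    total_epochs: int = 0

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def formatted(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.2f}")

    @property
    def mean_row(self):
        return self.frame[self.frame["fold"] == "Mean value"].iloc[0]


def stratified_kfold(labels: Sequence, k: int = 10, seed: int = 0,
                     modality: Sequence | None = None) -> FoldAssignment:
    """Stratified fold assignment: per-class counts across folds differ ≤ 1.

    Backed by scikit-learn's StratifiedKFold with seeded shuffling; every
    class must have at least k members.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer than k={k} members; "
            "cannot stratify"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.zeros(len(labels), dtype=np.int64)
    for i, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels), start=1):
        fold[val_idx] = i
    return FoldAssignment(fold=fold, labels=labels, k=k,
                          modality=np.asarray(modality) if modality is not None else None)


def _binary_counts(y_true: np.ndarray, y_pred: np.ndarray, positive) -> tuple[int, int, int, int]:
    t = y_true == positive
    p = y_pred == positive
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return tp, fp, tn, fn


def _safe_rate(num: float, den: float, name: str, cls) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined for class {cls!r} (zero denominator); "
                      "excluded from the average", RuntimeWarning)
        return None
    return 100.0 * num / den


def confusion_metrics(y_true: Sequence, y_pred: Sequence,
                      classes: Sequence | None = None,
                      average: str = "macro") -> dict:
    """Accuracy plus macro/micro-averaged one-vs-rest rates, all ×100.

    Returns a dict with keys accuracy, precision, recall, sensitivity,
    specificity, fpr, and per_class (the unaveraged one-vs-rest values).
    Undefined per-class rates are None and skipped by the macro average.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty inputs")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))

    accuracy = 100.0 * float(np.mean(y_true == y_pred))
    per_class: dict = {}
    agg = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for cls in classes:
        tp, fp, tn, fn = _binary_counts(y_true, y_pred, cls)
        agg["tp"] += tp; agg["fp"] += fp; agg["tn"] += tn; agg["fn"] += fn
        per_class[cls] = {
            "sensitivity": _safe_rate(tp, tp + fn, "sensitivity", cls),
            "specificity": _safe_rate(tn, tn + fp, "specificity", cls),
            "precision": _safe_rate(tp, tp + fp, "precision", cls),
            "fpr": _safe_rate(fp, fp + tn, "fpr", cls),
        }

    def macro(key: str) -> float | None:
        vals = [v[key] for v in per_class.values() if v[key] is not None]
        return float(np.mean(vals)) if vals else None

    def micro(key: str) -> float | None:
        tp, fp, tn, fn = agg["tp"], agg["fp"], agg["tn"], agg["fn"]
        num_den = {"sensitivity": (tp, tp + fn), "precision": (tp, tp + fp),
                   "specificity": (tn, tn + fp), "fpr": (fp, fp + tn)}[key]
        return _safe_rate(*num_den, key, "micro")

    avg = macro if average == "macro" else micro
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    sens = avg("sensitivity")
    return {
        "accuracy": accuracy,
        "precision": avg("precision"),
        "recall": sens,        # recall and sensitivity are the same quantity
        "sensitivity": sens,
        "specificity": avg("specificity"),
        "fpr": avg("fpr"),
        "per_class": per_class,
    }


def _binary_auc(y: np.ndarray, s: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = y.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc(y_true: Sequence, scores: np.ndarray) -> float:
    """Mann–Whitney area under the ROC curve, in [0, 1].

    Binary: ``y_true`` in {0,1} (or two labels) with 1D scores for the
    positive class.  Multiclass: 2D scores (n, m) → macro one-vs-rest.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim == 1:
        labels = np.unique(y)
        if labels.size != 2:
            raise ValueError("binary AUC needs exactly two classes present")
        return _binary_auc((y == labels.max()).astype(int), s)
    aucs = []
    for c in range(s.shape[1]):
        mask = y == c
        if mask.any() and (~mask).any():
            aucs.append(_binary_auc(mask.astype(int), s[:, c]))
    if not aucs:
        raise ValueError("AUC needs both classes present")
    return float(np.mean(aucs))


def cross_validate(dataset: tuple[np.ndarray, np.ndarray], mcnn_config,
                   k: int = 10, seed: int = 0, epochs_per_fold: int = 15,
                   class_names: Sequence[str] | None = None,
                   modality: Sequence | None = None) -> MetricsReport:
    """Train/evaluate one classifier per stratified fold; Table-style report.

    ``dataset`` is ``(X, y)`` with X shaped (n, channels, H, W).  Each fold
    trains a freshly initialized model for ``epochs_per_fold`` epochs (the
    default 15 over 10 folds accounts exactly 150 epochs) on the other k−1
    folds and is scored on the held-out fold.  The "Mean value" row is the
    exact arithmetic mean of the fold rows.
    """
    import pandas as pd
    from dataclasses import replace as dc_replace

    from pulmostage.mcnn import build_mcnn, train as mcnn_train

    x, y = np.asarray(dataset[0]), np.asarray(dataset[1], dtype=np.int64)
    assignment = stratified_kfold(y, k=k, seed=seed, modality=modality)

    rows, histories = [], []
    total_epochs = 0
    for fold_idx in range(1, k + 1):
        trn, val = assignment.split(fold_idx)
        cfg = dc_replace(mcnn_config, epochs=epochs_per_fold,
                         seed=int(mcnn_config.seed + fold_idx))
        model = build_mcnn(cfg, class_names=class_names)
        # no early stopping inside the fixed per-fold epoch budget
        model, hist = mcnn_train(model, (x[trn], y[trn]), cfg)
        total_epochs += len(hist.train_loss)
        histories.append(hist)

        probs = np.vstack([model.forward(x[val][i:i + 50])
                           for i in range(0, len(val), 50)])
        preds = probs.argmax(axis=1)
        metrics = confusion_metrics(y[val], preds, classes=np.arange(cfg.n_classes))
        try:
            fold_auc = 100.0 * auc(y[val], probs)
        except ValueError:
            fold_auc = np.nan
        rows.append({
            "fold": str(fold_idx),
            "accuracy": metrics["accuracy"],
            "precision": metrics["precision"],
            "recall": metrics["recall"],
            "sensitivity": metrics["sensitivity"],
            "specificity": metrics["specificity"],
            "fpr": metrics["fpr"],
            "auc": fold_auc,
        })

    frame = pd.DataFrame(rows)
    mean_row = {"fold": "Mean value"}
    for col in frame.columns[1:]:
        mean_row[col] = float(np.mean(frame[col].to_numpy(dtype=float)))
    frame = pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
    return MetricsReport(frame=frame, histories=histories, total_epochs=total_epochs)
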