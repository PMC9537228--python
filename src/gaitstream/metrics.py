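"""Classification metrics: confusion, per-class PRF/AUC, ROC curves.

Per-class "accuracy" is reported two ways, clearly labelled: ``recall``
(diagonal over row sum, the convention used when quoting per-class accuracy
of a multiclass classifier) and ``ovr_accuracy`` (one-vs-rest accuracy).
Macro accuracy is the unweighted mean of per-class recalls (balanced
accuracy); overall accuracy is trace over total. The two coincide only on
balanced test sets.

Zero-denominator convention: precision/recall/F1 are 0 when undefined, with
a warning. AUC of a class absent from the test set is NaN and is excluded
from the macro average with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_curve

from gaitstream.io import CLASSES


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics."""

    confusion: np.ndarray                       # (E, E) counts, rows = true class
    classes: tuple[str, ...]
    per_class: dict[str, np.ndarray]            # precision/recall/f1/auc/ovr_accuracy
    macro: dict[str, float]
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    n_samples: int = 0

    @property
    def overall_accuracy(self) -> float:
        return self.macro["overall_accuracy"]

    @property
    def macro_accuracy(self) -> float:
        return self.macro["macro_accuracy"]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": {k: [None if np.isnan(x) else float(x) for x in v]
                          for k, v in self.per_class.items()},
            "macro": {k: (None if np.isnan(v) else float(v)) for k, v in self.macro.items()},
            "n_samples": int(self.n_samples),
        }


def compute_metrics(
    y_true: np.ndarray,
    proba: np.ndarray,
    classes: tuple[str, ...] = CLASSES,
) -> MetricsReport:
    """Metrics from integer labels and predicted class probabilities."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    E = len(classes)
    y_pred = proba.argmax(axis=1)
    conf = confusion_matrix(y_true, y_pred, labels=np.arange(E))
    n = len(y_true)

    row_sums = conf.sum(axis=1)
    col_sums = conf.sum(axis=0)
    if np.any((row_sums == 0) | ((col_sums == 0) & (row_sums > 0))):
        warnings.warn(
            "some classes have zero true or predicted samples; undefined "
            "precision/recall/F1 reported as 0",
            UserWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=np.arange(E), zero_division=0
        )

    # one-vs-rest accuracy per class
    ovr_acc = np.empty(E)
    for k in range(E):
        tp = conf[k, k]
        fn = row_sums[k] - tp
        fp = col_sums[k] - tp
        tn = n - tp - fn - fp
        ovr_acc[k] = (tp + tn) / n if n else 0.0

    # one-vs-rest ROC/AUC from predicted probabilities
    aucs = np.full(E, np.nan)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(E):
        mask = y_true == k
        if mask.all() or not mask.any():
            warnings.warn(
                f"class {classes[k]!r} absent (or exclusive) in the test set; "
                "AUC undefined and excluded from the macro average",
                UserWarning,
                stacklevel=2,
            )
            continue
        fpr, tpr, _ = roc_curve(mask.astype(int), proba[:, k])
        curves[classes[k]] = (fpr, tpr)
        aucs[k] = _auc(fpr, tpr)

    per_class = {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": aucs,
        "ovr_accuracy": ovr_acc,
    }
    present = row_sums > 0
    macro = {
        "overall_accuracy": float(np.trace(conf) / n) if n else 0.0,
        "macro_accuracy": float(recall[present].mean()) if present.any() else 0.0,
        "precision": float(precision[present].mean()) if present.any() else 0.0,
        "recall": float(recall[present].mean()) if present.any() else 0.0,
        "f1": float(f1[present].mean()) if present.any() else 0.0,
        "auc": float(np.nanmean(aucs)) if np.any(~np.isnan(aucs)) else float("nan"),
    }
    return MetricsReport(
        confusion=conf,
        classes=tuple(classes),
        per_class=per_class,
        macro=macro,
        roc_curves=curves,
        n_samples=n,
    )


def evaluate(model, test_samples, classes: tuple[str, ...] = CLASSES) -> MetricsReport:
    """Run a fitted model on motion samples and compute the metric report."""
    from gaitstream.train import featurize_set  # local import to avoid a cycle

    S, Sp, y = featurize_set(test_samples, classes=classes)
    if len(test_samples) == 0:
        raise ValueError("test set is empty")
    proba = model.predict_proba(S, Sp)
    return compute_metrics(y.argmax(axis=1), proba, classes=classes)


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Mean per-fold metrics (NaN-aware for AUC) plus the summed confusion."""
    if not reports:
        raise ValueError("no fold reports to aggregate")
    classes = reports[0].classes
    conf = sum((r.confusion for r in reports), np.zeros_like(reports[0].confusion))
    n = int(sum(r.n_samples for r in reports))
    per_class = {}
    for key in reports[0].per_class:
        stacked = np.stack([r.per_class[key] for r in reports])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_class[key] = np.nanmean(stacked, axis=0)
    macro = {}
    for key in reports[0].macro:
        vals = np.array([r.macro[key] for r in reports], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            macro[key] = float(np.nanmean(vals))
    # pooled accuracies from the summed confusion are the stable aggregates
    macro["overall_accuracy"] = float(np.trace(conf) / n) if n else 0.0
    row = conf.sum(axis=1)
    present = row > 0
    diag = np.diag(conf)[present] / row[present]
    macro["macro_accuracy"] = float(diag.mean()) if present.any() else 0.0
    return MetricsReport(
        confusion=conf,
        classes=classes,
        per_class=per_class,
        macro=macro,
        roc_curves={},
        n_samples=n,
    )
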