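"""Per-class and macro-averaged classification metrics.

Each class is reduced one-vs-rest: accuracy = (TP+TN)/n, precision =
TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, and AUC the
one-vs-rest ranking of that class's posterior.  Macro values are unweighted
means over classes.  A class absent from the true labels has undefined AUC;
it is excluded from the macro AUC with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .labels import CLASS_NAMES

METRIC_COLUMNS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class MetricsReport:
    """Per-class table, macro averages and the raw confusion matrix."""

    per_class: pd.DataFrame        # index: class names; columns: METRIC_COLUMNS
    macro: dict[str, float]
    confusion: np.ndarray          # true classes on rows
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "per_class": {c: {m: _round(self.per_class.loc[c, m]) for m in METRIC_COLUMNS}
                          for c in self.per_class.index},
            "macro": {m: _round(v) for m, v in self.macro.items()},
            "confusion_matrix": self.confusion.tolist(),
            "n_samples": int(self.n_samples),
        }

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def save_confusion_csv(self, path: str | Path) -> Path:
        path = Path(path)
        names = list(self.per_class.index)
        pd.DataFrame(self.confusion, index=names, columns=names).to_csv(path)
        return path


def _round(v: float) -> float | None:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(round(v, 6))


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    posteriors: np.ndarray | None = None,
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> MetricsReport:
    """One-vs-rest metrics for a multiclass prediction.

    ``posteriors`` (rows normalized over classes) enables AUC; without it
    the AUC columns are NaN.  Deterministic.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    k = len(class_names)
    n = y_true.size
    if posteriors is not None:
        posteriors = np.asarray(posteriors, dtype=float)
        if posteriors.shape != (n, k):
            raise ValueError(f"posteriors must have shape {(n, k)}, got {posteriors.shape}")
        if not np.allclose(posteriors.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("posterior rows must sum to 1")

    cm = confusion_matrix(y_true, y_pred, labels=np.arange(k))
    rows = []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        acc = (tp + tn) / n if n else np.nan
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        auc = np.nan
        if posteriors is not None:
            present = np.any(y_true == c)
            if present and not np.all(y_true == c):
                auc = float(roc_auc_score((y_true == c).astype(int), posteriors[:, c]))
            else:
                warnings.warn(
                    f"class {class_names[c]!r} has no {'positive' if not present else 'negative'} "
                    "examples; AUC undefined and excluded from the macro average"
                )
        rows.append((acc, prec, rec, f1, auc))

    per_class = pd.DataFrame(rows, index=list(class_names), columns=list(METRIC_COLUMNS))
    macro = {}
    for m in METRIC_COLUMNS:
        vals = per_class[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        macro[m] = float(vals.mean()) if vals.size else float("nan")
    return MetricsReport(per_class=per_class, macro=macro, confusion=cm, n_samples=n)
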