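"""Evaluation surface: confusion matrices, one-vs-rest rates, ROC/AUC,
cross-entropy, cross-validation aggregation, patch-probability averaging.

Rates with empty denominators (a class absent from both truth and
prediction, say) are reported as ``None`` and flagged, never coerced to 0
or 1 — coercion would silently bias macro averages.  Macro summaries skip
absent entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


@dataclass
class ClassRates:
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    npv: Optional[float]
    f1: Optional[float]
    support: int
    undefined: List[str] = field(default_factory=list)


@dataclass
class MetricsReport:
    confusion: np.ndarray                  # (C, C), rows = truth
    per_class: List[ClassRates]
    accuracy: float
    level: str = "slide"
    macro_auc: Optional[float] = None
    macro_auc_ci: Optional[tuple] = None
    cross_entropy: Optional[float] = None

    def per_class_frame(self, class_names: Optional[List[str]] = None) -> pd.DataFrame:
        rows = [asdict(r) for r in self.per_class]
        df = pd.DataFrame(rows)
        df.insert(0, "class", class_names or list(range(len(rows))))
        return df

    def to_json(self) -> str:
        payload = {
            "level": self.level,
            "accuracy": self.accuracy,
            "macro_auc": self.macro_auc,
            "macro_auc_ci": self.macro_auc_ci,
            "cross_entropy": self.cross_entropy,
            "confusion": self.confusion.tolist(),
            "per_class": [asdict(r) for r in self.per_class],
        }
        return json.dumps(payload, indent=2)


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def confusion_and_rates(truth: Sequence[int], pred: Sequence[int],
                        n_classes: int, level: str = "slide") -> MetricsReport:
    """Confusion matrix plus one-vs-rest precision/recall/specificity/NPV/F1."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth/pred length mismatch")
    if truth.size and (truth.min() < 0 or truth.max() >= n_classes
                       or pred.min() < 0 or pred.max() >= n_classes):
        raise ValueError("labels outside [0, n_classes)")
    cm = _sk_confusion(truth, pred, labels=list(range(n_classes)))
    total = cm.sum()
    per_class = []
    for c in range(n_classes):
        tp = cm[c, c]
        fn = cm[c, :].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp)
        npv = _safe_div(tn, tn + fn)
        if precision is None or recall is None or (precision + recall) == 0:
            f1 = None if (precision is None or recall is None) else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        undefined = [name for name, v in
                     [("precision", precision), ("recall", recall),
                      ("specificity", specificity), ("npv", npv), ("f1", f1)]
                     if v is None]
        if undefined:
            logger.info("class %d: undefined rates %s (no support)", c, undefined)
        per_class.append(ClassRates(precision, recall, specificity, npv, f1,
                                    support=int(cm[c, :].sum()),
                                    undefined=undefined))
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    return MetricsReport(confusion=cm, per_class=per_class,
                         accuracy=accuracy, level=level)


def roc_auc(scores: np.ndarray, truth: Sequence[int], cls: int) -> Optional[float]:
    """One-vs-rest AUC for one class; None when the class is degenerate.

    Equals the Mann-Whitney pair statistic with ties counted one half.
    ``scores`` is the (n, C) per-class probability matrix (or an (n,) score
    column).
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=np.float64)
    col = scores if scores.ndim == 1 else scores[:, cls]
    y = (truth == cls).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        logger.info("class %d degenerate for AUC (all one outcome)", cls)
        return None
    return float(roc_auc_score(y, col))


def macro_auc(scores: np.ndarray, truth: Sequence[int],
              n_classes: int) -> Optional[float]:
    """Unweighted mean of the defined one-vs-rest AUCs."""
    vals = [roc_auc(scores, truth, c) for c in range(n_classes)]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


def roc_points(scores: np.ndarray, truth: Sequence[int], cls: int) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for one class."""
    truth = np.asarray(truth)
    col = scores if np.asarray(scores).ndim == 1 else np.asarray(scores)[:, cls]
    fpr, tpr, thr = roc_curve((truth == cls).astype(int), col)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def cross_entropy(probabilities: np.ndarray, truth: Sequence[int]) -> float:
    """Mean negative log-likelihood of the true class (natural log)."""
    P = np.asarray(probabilities, dtype=np.float64)
    truth = np.asarray(truth)
    if P.ndim != 2 or P.shape[0] != truth.shape[0]:
        raise ValueError("probability matrix / truth mismatch")
    picked = P[np.arange(len(truth)), truth]
    return float(-np.log(np.maximum(picked, PROB_FLOOR)).mean())


def cv_mean_ci(values: Sequence[float], confidence_z: float = 1.96) -> dict:
    """Across-fold mean with a normal-approximation 95% CI."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least 2 folds")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return {"mean": mean, "ci_low": mean - confidence_z * se,
            "ci_high": mean + confidence_z * se, "k": int(vals.size)}


def cv_pooled_auc(folds: Sequence[dict], n_classes: int) -> dict:
    """Single ROC summary from the concatenated outputs of all folds.

    Each fold is a dict with keys ``truth`` (labels) and ``scores``
    ((n, C) probabilities).  Mirrors reporting that pools fold predictions
    into one curve instead of averaging per-fold AUCs.
    """
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    for i, f in enumerate(folds, start=1):
        if len(np.asarray(f["truth"])) == 0:
            raise ValueError(f"fold {i} is empty")
    truth = np.concatenate([np.asarray(f["truth"]) for f in folds])
    scores = np.vstack([np.asarray(f["scores"]) for f in folds])
    per_class = {c: roc_auc(scores, truth, c) for c in range(n_classes)}
    return {"per_class_auc": per_class,
            "macro_auc": macro_auc(scores, truth, n_classes),
            "n": int(len(truth))}


def cv_aggregate(per_fold, mode: str = "mean_ci", n_classes: Optional[int] = None):
    """Aggregate fold-level results: ``mean_ci`` over scalars or ``pooled`` ROC."""
    if mode == "mean_ci":
        return cv_mean_ci(per_fold)
    if mode == "pooled":
        if n_classes is None:
            raise ValueError("pooled mode needs n_classes")
        return cv_pooled_auc(per_fold, n_classes)
    raise ValueError(f"unknown mode {mode!r}")


def average_patch_probabilities(patch_probs: np.ndarray) -> np.ndarray:
    """Slide probability vector as the mean of per-patch probability rows.

    This is the report/visualization path; the attention-pooled classifier
    is the primary prediction path.
    """
    P = np.asarray(patch_probs, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("need at least one patch probability row")
    mean = P.mean(axis=0)
    s = mean.sum()
    if s > 0 and not np.isclose(s, 1.0):
        mean = mean / s
    return mean
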