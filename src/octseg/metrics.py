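"""Pixel-classification evaluation: confusion metrics, ROC/AUC, CV folds.

Segmentation quality is scored from pixel confusion counts:

    precision   = tp / (tp + fp)
    sensitivity = tp / (tp + fn)
    specificity = tn / (fp + tn)
    F1          = 2 tp / (2 tp + fp + fn)

A metric whose denominator is zero is reported as 0 with a warning, so
batch evaluation over many images never aborts. ROC curves sweep all
distinct score thresholds; AUC is the trapezoidal area, equal to the
pairwise rank statistic P(score_pos > score_neg) + 0.5 P(tie), ranging
from 0.5 (chance) to 1.0 (perfect discrimination).

Cross-validation is partitioned at *patient* level: all scans of one
patient land in the same fold, preventing leakage between folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    sensitivity: float
    specificity: float
    f1: float

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision * scale,
            "sensitivity": self.sensitivity * scale,
            "specificity": self.specificity * scale,
            "f1": self.f1 * scale,
        }


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray           # 1 - specificity
    tpr: np.ndarray           # sensitivity
    auc: float


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) pixel counts for binary rasters."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred > 0
    t = truth > 0
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return tp, fp, fn, tn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics_report(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise ValueError("all confusion counts are zero")
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=_safe_ratio(tp, tp + fp, "precision"),
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, fp + tn, "specificity"),
        f1=_safe_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    )


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    return metrics_report(*confusion_counts(pred, truth))


def aggregate_reports(reports: list[MetricsReport],
                      mode: str = "per-image") -> dict:
    """mean ± sd of the four metrics across images, or pooled-pixel metrics.

    ``per-image`` (default) averages each metric over images, matching the
    mean ± sd presentation conventional in segmentation tables;
    ``pooled`` sums confusion counts first and derives metrics once.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    if mode == "pooled":
        tp = sum(r.tp for r in reports)
        fp = sum(r.fp for r in reports)
        fn = sum(r.fn for r in reports)
        tn = sum(r.tn for r in reports)
        return {"mode": mode, **metrics_report(tp, fp, fn, tn).as_dict()}
    if mode != "per-image":
        raise ValueError("mode must be 'per-image' or 'pooled'")
    out: dict = {"mode": mode, "n_images": len(reports)}
    for key in ("precision", "sensitivity", "specificity", "f1"):
        vals = np.array([getattr(r, key) for r in reports])
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return out


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> ROCResult:
    """ROC over all distinct thresholds and trapezoidal AUC."""
    scores = np.ravel(np.asarray(scores, dtype=np.float64))
    truth = np.ravel(np.asarray(truth) > 0)
    if truth.all() or not truth.any():
        raise ValueError("AUC undefined: truth contains a single class")
    fpr, tpr, thresholds = _sk_roc_curve(truth.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class FoldAssignment:
    folds: list[list[str]] = field(default_factory=list)  # patient ids per fold

    def test_entries(self, entries: list[dict], fold: int) -> list[dict]:
        members = set(self.folds[fold])
        return [e for e in entries if e["patient_id"] in members]

    def train_entries(self, entries: list[dict], fold: int) -> list[dict]:
        members = set(self.folds[fold])
        return [e for e in entries if e["patient_id"] not in members]


def crossval_folds(entries: list[dict], k: int, seed: int) -> FoldAssignment:
    """Deterministic k-fold partition of *patients* (no patient spans folds)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    patients = sorted({e["patient_id"] for e in entries})
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    shuffled = [patients[i] for i in order]
    folds = [sorted(shuffled[i::k]) for i in range(k)]
    return FoldAssignment(folds=folds)
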