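"""Segmentation and agreement metrics.

Pixel precision here is the micro-averaged fraction of correctly
classified pixels, Pre = True_p / (True_p + False_p), counted jointly
over all classes. MIoU is the per-class intersection-over-union averaged
over classes; classes absent from both masks (empty union) are excluded
from the mean to avoid 0/0.

Agreement between automated and manual trait measurements is summarized
by R^2 and RMSE. Two R^2 conventions are exposed: the identity-agreement
form (residuals about the y = x line, the default) and the ordinary
least-squares regression form; they coincide only when the estimates are
unbiased. The trait correlation matrix is plain Pearson r with two-sided
p-values from the t transform on n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion_counts", "pixel_precision",
    "per_class_iou", "mean_iou", "r_squared", "rmse",
    "pearson_correlation_matrix", "evaluate_masks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    true_p: int
    false_p: int

    @property
    def total(self) -> int:
        return self.true_p + self.false_p


@dataclass
class MetricsReport:
    precision: float
    per_class_iou: dict[int, float]
    miou: float
    r2: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "per_class_iou": {str(k): v for k, v in self.per_class_iou.items()},
            "miou": self.miou,
            "r2": dict(self.r2),
            "rmse": dict(self.rmse),
        }


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.size == 0:
        raise ValueError("empty masks")
    return pred, gt


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred, gt = _check_pair(pred, gt)
    tp = int((pred == gt).sum())
    return ConfusionCounts(true_p=tp, false_p=pred.size - tp)


def pixel_precision(pred: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of pixels classified correctly, all classes jointly."""
    c = confusion_counts(pred, gt)
    return c.true_p / c.total


def per_class_iou(pred: np.ndarray, gt: np.ndarray, num_classes: int) -> dict[int, float]:
    """IoU per class; classes with empty union are omitted."""
    pred, gt = _check_pair(pred, gt)
    if pred.max(initial=0) >= num_classes or gt.max(initial=0) >= num_classes:
        raise ValueError("labels exceed num_classes")
    out: dict[int, float] = {}
    for k in range(num_classes):
        p = pred == k
        g = gt == k
        union = int((p | g).sum())
        if union:
            out[k] = int((p & g).sum()) / union
    return out


def mean_iou(pred: np.ndarray, gt: np.ndarray, num_classes: int) -> float:
    ious = per_class_iou(pred, gt, num_classes)
    if not ious:
        raise ValueError("every class has empty union; MIoU undefined")
    return float(np.mean(list(ious.values())))


def r_squared(estimated, reference, convention: str = "agreement") -> float:
    """Coefficient of determination between estimates and reference values.

    ``"agreement"``: 1 - SS_res/SS_tot with residuals = estimated - reference
    (about the identity line). ``"regression"``: squared Pearson r, the OLS
    fit R^2.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    if est.size < 2:
        raise ValueError("need at least two points")
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("reference series is constant; R^2 undefined")
    if convention == "agreement":
        ss_res = float(((est - ref) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    if convention == "regression":
        return float(stats.pearsonr(est, ref).statistic ** 2)
    raise ValueError(f"unknown convention {convention!r}")


def rmse(estimated, reference) -> float:
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("length mismatch")
    if est.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def pearson_correlation_matrix(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values over table columns.

    Rows are observational units (varieties), columns are traits. Requires
    at least 3 complete rows and non-constant columns.
    """
    df = pd.DataFrame(traits)
    if df.isna().any().any():
        raise ValueError("missing cells; complete the table first")
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    if (df.std(ddof=0) == 0).any():
        bad = list(df.columns[df.std(ddof=0) == 0])
        raise ValueError(f"zero-variance columns: {bad}")
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            res = stats.pearsonr(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def evaluate_masks(pred_masks, gt_masks, num_classes: int = 3) -> MetricsReport:
    """Aggregate precision and MIoU over paired mask sequences.

    Counts are pooled over all pixels of all pairs (dataset-level metric),
    matching evaluation at full mask resolution.
    """
    preds = list(pred_masks)
    gts = list(gt_masks)
    if len(preds) != len(gts) or not preds:
        raise ValueError("need equally many prediction and reference masks")
    tp = tot = 0
    inter = np.zeros(num_classes, dtype=np.int64)
    union = np.zeros(num_classes, dtype=np.int64)
    for pr, gt in zip(preds, gts):
        pr, gt = _check_pair(pr, gt)
        tp += int((pr == gt).sum())
        tot += pr.size
        for k in range(num_classes):
            p = pr == k
            g = gt == k
            inter[k] += int((p & g).sum())
            union[k] += int((p | g).sum())
    ious = {k: inter[k] / union[k] for k in range(num_classes) if union[k]}
    return MetricsReport(precision=tp / tot, per_class_iou=ious,
                         miou=float(np.mean(list(ious.values()))))
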