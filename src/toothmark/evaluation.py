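"""Metrics, repeated stratified cross-validation and localization scoring.

Classification is scored with accuracy, precision, recall and F1 from
the standard 2x2 confusion table (tooth-marked = positive class),
aggregated as mean +/- standard deviation over k-fold cross-validation
repeated several times with independent partitions (5 repeats of
4 folds by default).  Localization is scored on synthetic ground truth
as the fraction of predicted boxes that overlap a planted mark at a
given IoU threshold, plus the recall of planted marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .preprocess import TongueSample

__all__ = [
    "ConfusionCounts",
    "MetricsResult",
    "MetricsReport",
    "CVPlan",
    "confusion_counts",
    "metrics",
    "cross_validate",
    "box_iou",
    "localization_hit_rate",
    "render_overlay",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsResult:
    """The four ratios; zero-denominator cases are 0 and flagged undefined."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class MetricsReport:
    """Per-fold metric results with mean and std across folds x repeats."""

    per_fold: list[MetricsResult] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        return {
            k: float(np.mean([m.as_dict()[k] for m in self.per_fold]))
            for k in ("accuracy", "precision", "recall", "f1")
        }

    @property
    def std(self) -> dict[str, float]:
        return {
            k: float(np.std([m.as_dict()[k] for m in self.per_fold]))
            for k in ("accuracy", "precision", "recall", "f1")
        }


@dataclass
class CVPlan:
    """Repeated k-fold protocol (defaults: 4 folds, 5 repeats, stratified)."""

    k: int = 4
    repeats: int = 5
    seed: int = 0
    stratified: bool = True


def confusion_counts(preds, labels) -> ConfusionCounts:
    """2x2 tally with tooth-marked (1) as the positive class."""
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    return ConfusionCounts(
        TP=int(((preds == 1) & (labels == 1)).sum()),
        FP=int(((preds == 1) & (labels == 0)).sum()),
        TN=int(((preds == 0) & (labels == 0)).sum()),
        FN=int(((preds == 0) & (labels == 1)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricsResult:
    """Accuracy, precision, recall and F1 from a confusion table.

    Precision with no predicted positives, recall with no actual
    positives, and F1 when precision+recall is zero are reported as 0
    and flagged in ``undefined`` so aggregation stays total.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of an empty evaluation")
    undefined: set[str] = set()
    accuracy = (c.TP + c.TN) / c.total
    if c.TP + c.FP:
        precision = c.TP / (c.TP + c.FP)
    else:
        precision = 0.0
        undefined.add("precision")
    if c.TP + c.FN:
        recall = c.TP / (c.TP + c.FN)
    else:
        recall = 0.0
        undefined.add("recall")
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        undefined.add("f1")
    return MetricsResult(accuracy, precision, recall, f1, frozenset(undefined))


def cross_validate(
    samples: list[TongueSample],
    plan: CVPlan,
    estimator,
    return_folds: bool = False,
):
    """Repeated k-fold cross-validation of an (unfitted) estimator.

    Each repeat draws an independent shuffled partition; folds are
    stratified by label when ``plan.stratified``.  Returns a
    :class:`MetricsReport` (and the per-repeat fold index lists when
    ``return_folds``).
    """
    labels = np.array([s.label for s in samples])
    if plan.stratified:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < plan.k:
            raise ValueError(
                f"need >= k={plan.k} samples per class for stratified folds, got {counts}"
            )
    report = MetricsReport()
    fold_indices = []
    for rep in range(plan.repeats):
        splitter = StratifiedKFold(
            n_splits=plan.k, shuffle=True, random_state=(plan.seed + rep) % (2**32)
        )
        strat_y = labels if plan.stratified else np.zeros_like(labels)
        rep_folds = []
        for tr, va in splitter.split(np.zeros(len(samples)), strat_y):
            if len(np.unique(labels[tr])) < 2:
                raise ValueError(
                    "a training fold lost one class entirely; enable stratification"
                )
            est = clone(estimator)
            est.fit([samples[i] for i in tr])
            preds = est.predict([samples[i] for i in va])
            report.per_fold.append(metrics(confusion_counts(preds, labels[va])))
            rep_folds.append((tr, va))
        fold_indices.append(rep_folds)
    if return_folds:
        return report, fold_indices
    return report


def box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """IoU of two half-open (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def _as_xywh(box) -> tuple[int, int, int, int]:
    if hasattr(box, "x_min"):
        return (box.x_min, box.y_min, box.w, box.h)
    return tuple(box)  # type: ignore[return-value]


@dataclass(frozen=True)
class LocalizationScore:
    hit_rate: float  # predicted boxes overlapping some truth box
    truth_recall: float  # truth boxes overlapped by some prediction
    n_pred: int
    n_truth: int


def localization_hit_rate(
    pred_boxes_per_image: list[list],
    truth_boxes_per_image: list[list],
    iou_threshold: float = 0.3,
) -> LocalizationScore:
    """Fraction of predicted boxes matching a planted mark at IoU >= threshold.

    Predicted entries may be ``(box, score)`` pairs or bare boxes.  Also
    reports the recall of truth boxes.  With no predictions the hit
    rate is 0 by convention (and likewise for recall with no truth).
    """
    if len(pred_boxes_per_image) != len(truth_boxes_per_image):
        raise ValueError("prediction and truth lists must align per image")
    hits = n_pred = covered = n_truth = 0
    for preds, truths in zip(pred_boxes_per_image, truth_boxes_per_image):
        pboxes = [
            _as_xywh(p[0] if isinstance(p, tuple) and len(p) == 2 and not np.isscalar(p[0]) else p)
            for p in preds
        ]
        tboxes = [_as_xywh(t) for t in (truths or [])]
        n_pred += len(pboxes)
        n_truth += len(tboxes)
        for p in pboxes:
            if any(box_iou(p, t) >= iou_threshold for t in tboxes):
                hits += 1
        for t in tboxes:
            if any(box_iou(p, t) >= iou_threshold for p in pboxes):
                covered += 1
    return LocalizationScore(
        hit_rate=hits / n_pred if n_pred else 0.0,
        truth_recall=covered / n_truth if n_truth else 0.0,
        n_pred=n_pred,
        n_truth=n_truth,
    )


def render_overlay(
    image: np.ndarray,
    boxes: list,
    scores: list[float] | None = None,
    color: tuple[int, int, int] = (255, 220, 0),
) -> np.ndarray:
    """Burn candidate boxes (and scores) into a copy of the image."""
    canvas = Image.fromarray(np.asarray(image)).convert("RGB")
    draw = ImageDraw.Draw(canvas)
    for i, box in enumerate(boxes):
        x, y, w, h = _as_xywh(box)
        draw.rectangle([x, y, x + w - 1, y + h - 1], outline=color, width=2)
        if scores is not None:
            draw.text((x + 2, y + 2), f"{scores[i]:.2f}", fill=color)
    return np.asarray(canvas)
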