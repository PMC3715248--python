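"""Matching-matrix evaluation: per-class hit/FP rates, precision, accuracy.

For truth/prediction label-map pairs a 5×5 matching (confusion) matrix is
counted at pixel level, rows = truth, columns = prediction, in the fixed
class order FRUIT, STEM, LEAF, BRANCH, BACKGROUND. From it:

* TP rate_i (hit rate / recall)  = 100 · tP_i / (row total)_i
* FP rate_i                      = 100 · fP_i / (total − row_i)
* Precision_i                    = 100 · tP_i / (tP_i + fP_i)
* Accuracy                       = 100 · trace / total
* Error rate                     = 100 − Accuracy

where tP_i is the diagonal entry and fP_i the column sum minus the
diagonal. All metrics are percentages; a metric whose denominator is zero
(a class absent from truth, or never predicted) is flagged undefined
(``None``) rather than silently zeroed. ROC points are per class per scene
on [0, 100] axes; perfect classification sits at (0, 100).

Cross-scene summaries are arithmetic means over scenes, reported to one
decimal with half-away-from-zero rounding; against a baseline summary the
improvement in percentage points per class and the accuracy ratio are
reported the same way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import DimensionMismatchError, VinesegError
from .image_model import EVAL_CLASSES, LabelMap, VineClass

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "tp_rate",
    "fp_rate",
    "precision_class",
    "accuracy_and_error",
    "scene_report",
    "roc_points",
    "aggregate_scenes",
    "ScenesSummary",
    "round_half_away",
]

log = logging.getLogger(__name__)

CLASS_ORDER = EVAL_CLASSES
CLASS_NAMES = tuple(c.name for c in CLASS_ORDER)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (1.25 -> 1.3, -1.25 -> -1.3)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP) if x >= 0 else \
        -(Decimal(str(-x)).quantize(q, rounding=ROUND_HALF_UP))
    return float(d)


@dataclass
class ConfusionMatrix:
    """5×5 pixel-count matching matrix (rows truth, columns prediction)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (5, 5):
            raise DimensionMismatchError(f"confusion matrix must be 5×5, got {c.shape}")
        if np.any(c < 0):
            raise VinesegError("negative counts in confusion matrix")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, i: int) -> int:
        return int(self.counts[i].sum())

    def col_total(self, i: int) -> int:
        return int(self.counts[:, i].sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fp(self, i: int) -> int:
        return self.col_total(i) - self.tp(i)


def _class_index(i) -> int:
    if isinstance(i, VineClass):
        i = CLASS_ORDER.index(i)
    if not (0 <= int(i) < 5):
        raise IndexError(f"class index out of range: {i}")
    return int(i)


def confusion(
    pred: LabelMap, truth: LabelMap, ignore=(VineClass.UNLABELED,)
) -> ConfusionMatrix:
    """Count pixels by (truth class, predicted class).

    Pixels whose truth class is in ``ignore`` are excluded.
    """
    if pred.shape != truth.shape:
        raise DimensionMismatchError(
            f"prediction shape {pred.shape} does not match truth shape {truth.shape}"
        )
    keep = np.ones(truth.values.shape, dtype=bool)
    for cls in ignore:
        keep &= truth.values != int(cls)
    t = truth.values[keep].astype(np.int64)
    p = pred.values[keep].astype(np.int64)
    if np.any(t > 4):
        raise VinesegError("truth contains non-evaluation classes outside the ignore set")
    if np.any(p > 4):
        raise VinesegError("prediction contains UNLABELED pixels; complete it first")
    counts = np.bincount(t * 5 + p, minlength=25).reshape(5, 5)
    return ConfusionMatrix(counts)


def tp_rate(cm: ConfusionMatrix, i) -> float | None:
    """Hit rate of class i in percent; None if the class is absent."""
    i = _class_index(i)
    row = cm.row_total(i)
    if row == 0:
        return None
    return 100.0 * cm.tp(i) / row


def fp_rate(cm: ConfusionMatrix, i) -> float | None:
    """FP rate of class i in percent; None if no out-of-class pixels exist."""
    i = _class_index(i)
    outside = cm.total - cm.row_total(i)
    if outside == 0:
        return None
    return 100.0 * cm.fp(i) / outside


def precision_class(cm: ConfusionMatrix, i) -> float | None:
    """Precision of class i in percent; None if the class was never predicted."""
    i = _class_index(i)
    predicted = cm.tp(i) + cm.fp(i)
    if predicted == 0:
        return None
    return 100.0 * cm.tp(i) / predicted


def accuracy_and_error(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy %, error rate %); the two sum to 100."""
    total = cm.total
    if total == 0:
        raise VinesegError("empty confusion matrix")
    trace = float(np.trace(cm.counts))
    acc = 100.0 * trace / total
    return acc, 100.0 - acc


@dataclass
class MetricsReport:
    """Per-scene metrics; rates in percent, None marks an undefined metric."""

    scene_id: str
    tp_rate: dict = field(default_factory=dict)  # class name -> % or None
    fp_rate: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)
    accuracy: float = float("nan")
    error_rate: float = float("nan")

    def to_json(self) -> dict:
        return {
            "scene_id": self.scene_id,
            "tp_rate": self.tp_rate,
            "fp_rate": self.fp_rate,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
        }

    @classmethod
    def from_json(cls, data: dict) -> "MetricsReport":
        return cls(
            scene_id=data["scene_id"],
            tp_rate=dict(data.get("tp_rate", {})),
            fp_rate=dict(data.get("fp_rate", {})),
            precision=dict(data.get("precision", {})),
            accuracy=data["accuracy"],
            error_rate=data["error_rate"],
        )


def scene_report(pred: LabelMap, truth: LabelMap, scene_id: str = "scene") -> MetricsReport:
    """Build the full metrics report for one scene from its matching matrix."""
    cm = confusion(pred, truth)
    acc, err = accuracy_and_error(cm)
    return MetricsReport(
        scene_id=scene_id,
        tp_rate={name: tp_rate(cm, i) for i, name in enumerate(CLASS_NAMES)},
        fp_rate={name: fp_rate(cm, i) for i, name in enumerate(CLASS_NAMES)},
        precision={name: precision_class(cm, i) for i, name in enumerate(CLASS_NAMES)},
        accuracy=acc,
        error_rate=err,
    )


def roc_points(reports) -> list[tuple[str, str, float, float]]:
    """One (class, scene, FP rate, TP rate) point per class per scene.

    Entries with an undefined rate are skipped with a warning.
    """
    reports = list(reports)
    if not reports:
        raise VinesegError("no reports given")
    points = []
    for rep in reports:
        for name in CLASS_NAMES:
            fp = rep.fp_rate.get(name)
            tp = rep.tp_rate.get(name)
            if fp is None or tp is None:
                log.warning("skipping undefined ROC point for %s in %s", name, rep.scene_id)
                continue
            points.append((name, rep.scene_id, float(fp), float(tp)))
    return points


@dataclass
class ScenesSummary:
    """Cross-scene arithmetic means, one decimal, half away from zero."""

    n_scenes: int
    mean_precision: dict
    mean_tp_rate: dict
    mean_fp_rate: dict
    mean_accuracy: float
    improvement_points: dict | None = None  # vs baseline, per class
    accuracy_ratio: float | None = None

    def to_json(self) -> dict:
        return {
            "n_scenes": self.n_scenes,
            "mean_precision": self.mean_precision,
            "mean_tp_rate": self.mean_tp_rate,
            "mean_fp_rate": self.mean_fp_rate,
            "mean_accuracy": self.mean_accuracy,
            "improvement_points": self.improvement_points,
            "accuracy_ratio": self.accuracy_ratio,
        }


def _mean_rounded(values) -> float | None:
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    if len(vals) < len(list(values)):
        log.warning("undefined entries skipped in cross-scene mean")
    total = sum(Decimal(str(v)) for v in vals) / len(vals)
    return round_half_away(float(total), 1)


def aggregate_scenes(reports, baseline: "ScenesSummary | None" = None) -> ScenesSummary:
    """Mean per-class precision / hit rate / FP rate and mean accuracy.

    With a ``baseline`` summary, also reports per-class precision
    improvement in percentage points and the accuracy ratio, both to one
    decimal.
    """
    reports = list(reports)
    if not reports:
        raise VinesegError("need at least one report")
    keysets = {frozenset(r.precision) for r in reports}
    if len(keysets) > 1:
        raise VinesegError("mixed class sets across reports")

    summary = ScenesSummary(
        n_scenes=len(reports),
        mean_precision={
            name: _mean_rounded([r.precision.get(name) for r in reports])
            for name in CLASS_NAMES
        },
        mean_tp_rate={
            name: _mean_rounded([r.tp_rate.get(name) for r in reports])
            for name in CLASS_NAMES
        },
        mean_fp_rate={
            name: _mean_rounded([r.fp_rate.get(name) for r in reports])
            for name in CLASS_NAMES
        },
        mean_accuracy=_mean_rounded([r.accuracy for r in reports]),
    )
    if baseline is not None:
        summary.improvement_points = {}
        for name in CLASS_NAMES:
            ours, theirs = summary.mean_precision[name], baseline.mean_precision.get(name)
            summary.improvement_points[name] = (
                None if ours is None or theirs is None
                else round_half_away(ours - theirs, 1)
            )
        if baseline.mean_accuracy:
            summary.accuracy_ratio = round_half_away(
                summary.mean_accuracy / baseline.mean_accuracy, 1
            )
    return summary
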