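"""Published six-scene field-trial scores, as worked-example inputs.

The sequential masking classifier was originally validated on six Cabernet
Sauvignon vineyard scenes (2,448 × 2,050 px) that were hand-labelled and
scored per class; the same scenes were also scored with the single-pass
RGB-only K-means baseline. The imagery itself was never deposited, but the
per-scene score tables were published, and the cross-scene aggregation in
:mod:`vineseg.evaluation` can be exercised against them.

Values are percentages as printed. Note one printed rounding quirk: the
baseline accuracy/error pair for scene 4 sums to 99.9, not 100, so reports
built here carry the printed values verbatim rather than re-deriving one
from the other.
"""

from __future__ import annotations

from .evaluation import MetricsReport

__all__ = ["sequential_reports", "rgb_baseline_reports"]

_SCENES = ["scene-1", "scene-2", "scene-3", "scene-4", "scene-5", "scene-6"]

# sequential masking classifier, per class per scene
_SEQ_TP = {
    "FRUIT": [76.5, 67.7, 77.1, 58.9, 61.1, 68.6],
    "STEM": [94.0, 88.8, 85.1, 84.3, 78.5, 66.0],
    "LEAF": [90.0, 83.7, 80.6, 68.7, 77.0, 92.1],
    "BRANCH": [28.0, 15.0, 34.0, 26.1, 39.8, 2.8],
    "BACKGROUND": [91.2, 79.5, 48.6, 82.3, 66.2, 64.5],
}
_SEQ_FP = {
    "FRUIT": [0.6, 2.9, 0.6, 0.1, 0.2, 2.1],
    "STEM": [2.6, 4.4, 6.75, 1.6, 4.1, 5.1],
    "LEAF": [6.9, 10.5, 16.8, 8.5, 16.8, 26.0],
    "BRANCH": [4.7, 7.9, 15.1, 21.5, 15.4, 2.9],
    "BACKGROUND": [1.5, 1.8, 1.8, 4.9, 3.0, 2.2],
}
_SEQ_PRECISION = {
    "FRUIT": [95.0, 77.1, 93.4, 93.6, 98.0, 80.9],
    "STEM": [72.6, 58.3, 42.5, 61.1, 57.2, 51.6],
    "LEAF": [93.8, 89.5, 80.9, 96.1, 86.0, 79.2],
    "BRANCH": [7.1, 4.5, 6.8, 1.0, 8.7, 4.5],
    "BACKGROUND": [95.7, 94.0, 93.2, 78.4, 83.4, 90.6],
}
_SEQ_ACCURACY = [88.1, 79.2, 68.3, 70.9, 71.5, 76.5]
_SEQ_ERROR = [11.9, 20.8, 31.7, 29.1, 28.5, 23.5]

# RGB-only K=5 baseline; only precision and accuracy/error were published
_BASE_PRECISION = {
    "FRUIT": [89.3, 76.1, 43.9, 54.7, 97.8, 72.9],
    "STEM": [12.1, 11.5, 2.4, 5.1, 18.6, 9.1],
    "LEAF": [77.9, 65.1, 5.0, 93.8, 84.7, 19.0],
    "BRANCH": [1.9, 1.0, 1.5, 1.2, 10.8, 1.21],
    "BACKGROUND": [79.1, 85.4, 76.8, 56.8, 23.7, 78.0],
}
_BASE_ACCURACY = [37.4, 28.4, 15.4, 52.1, 58.0, 19.3]
_BASE_ERROR = [62.6, 71.6, 84.6, 47.8, 42.0, 80.7]


def sequential_reports() -> list[MetricsReport]:
    """Per-scene reports of the sequential masking classifier (six scenes)."""
    return [
        MetricsReport(
            scene_id=_SCENES[s],
            tp_rate={cls: _SEQ_TP[cls][s] for cls in _SEQ_TP},
            fp_rate={cls: _SEQ_FP[cls][s] for cls in _SEQ_FP},
            precision={cls: _SEQ_PRECISION[cls][s] for cls in _SEQ_PRECISION},
            accuracy=_SEQ_ACCURACY[s],
            error_rate=_SEQ_ERROR[s],
        )
        for s in range(6)
    ]


def rgb_baseline_reports() -> list[MetricsReport]:
    """Per-scene reports of the RGB-only baseline (six scenes).

    Hit and FP rates were not published for the baseline, so those dicts
    are empty and excluded from aggregation.
    """
    return [
        MetricsReport(
            scene_id=_SCENES[s],
            tp_rate={},
            fp_rate={},
            precision={cls: _BASE_PRECISION[cls][s] for cls in _BASE_PRECISION},
            accuracy=_BASE_ACCURACY[s],
            error_rate=_BASE_ERROR[s],
        )
        for s in range(6)
    ]
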