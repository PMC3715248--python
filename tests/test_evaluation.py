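"""Matching-matrix metrics, ROC export and cross-scene aggregation."""

import numpy as np
import pytest

from vineseg import field_study
from vineseg.errors import DimensionMismatchError, VinesegError
from vineseg.evaluation import (
    CLASS_NAMES,
    ConfusionMatrix,
    MetricsReport,
    accuracy_and_error,
    aggregate_scenes,
    confusion,
    fp_rate,
    precision_class,
    roc_points,
    round_half_away,
    tp_rate,
)
from vineseg.image_model import LabelMap, VineClass


def _lm(codes):
    return LabelMap(np.asarray(codes, dtype=np.uint8))


def _random_cm(rng):
    return ConfusionMatrix(rng.integers(0, 50, size=(5, 5)))


def test_confusion_by_hand():
    truth = _lm([[int(VineClass.LEAF), int(VineClass.LEAF), int(VineClass.FRUIT)]])
    pred = _lm([[int(VineClass.LEAF), int(VineClass.FRUIT), int(VineClass.FRUIT)]])
    cm = confusion(pred, truth)
    L, F = 2, 0
    assert cm.counts[L, L] == 1
    assert cm.counts[L, F] == 1
    assert cm.counts[F, F] == 1
    assert cm.total == 3


def test_confusion_matches_double_loop(rng):
    truth = _lm(rng.integers(0, 5, size=(17, 13)))
    pred = _lm(rng.integers(0, 5, size=(17, 13)))
    cm = confusion(pred, truth)
    brute = np.zeros((5, 5), dtype=int)
    for r in range(17):
        for c in range(13):
            brute[truth.values[r, c], pred.values[r, c]] += 1
    assert np.array_equal(cm.counts, brute)


def test_confusion_ignores_unlabeled_truth(rng):
    truth_vals = rng.integers(0, 5, size=(10, 10))
    truth_vals[0] = int(VineClass.UNLABELED)
    pred = _lm(rng.integers(0, 5, size=(10, 10)))
    cm = confusion(pred, _lm(truth_vals))
    assert cm.total == 90


def test_confusion_shape_mismatch(rng):
    with pytest.raises(DimensionMismatchError):
        confusion(_lm(np.zeros((3, 3))), _lm(np.zeros((4, 4))))


def test_rates_match_formulas(rng):
    cm = _random_cm(rng)
    total = cm.total
    for i in range(5):
        row, col, diag = cm.counts[i].sum(), cm.counts[:, i].sum(), cm.counts[i, i]
        if row:
            assert tp_rate(cm, i) == pytest.approx(100.0 * diag / row)
        if total - row:
            assert fp_rate(cm, i) == pytest.approx(100.0 * (col - diag) / (total - row))
        if col:
            assert precision_class(cm, i) == pytest.approx(100.0 * diag / col)


def test_rate_anchors():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 9
    counts[0, 1] = 1  # row 0 total 10
    counts[1, 0] = 2
    counts[1, 1] = 98  # 100 out-of-class-0 pixels
    cm = ConfusionMatrix(counts)
    assert tp_rate(cm, 0) == pytest.approx(90.0)
    assert fp_rate(cm, 0) == pytest.approx(2.0)
    assert precision_class(cm, 0) == pytest.approx(100 * 9 / 11)
    # perfect prediction: tp 100, fp 0, precision 100
    perfect = ConfusionMatrix(np.diag([5, 5, 5, 5, 5]))
    for i in range(5):
        assert tp_rate(perfect, i) == 100.0
        assert fp_rate(perfect, i) == 0.0
        assert precision_class(perfect, i) == 100.0


def test_undefined_metrics_flagged():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 10
    cm = ConfusionMatrix(counts)
    assert tp_rate(cm, 1) is None  # class absent from truth
    assert precision_class(cm, 1) is None  # never predicted
    assert fp_rate(cm, 1) == 0.0  # never predicted -> zero FP rate
    assert fp_rate(cm, 0) is None  # no out-of-class pixels


def test_accuracy_error_complementarity(rng):
    for _ in range(20):
        cm = _random_cm(rng)
        acc, err = accuracy_and_error(cm)
        assert acc + err == pytest.approx(100.0, abs=1e-9)
        # sum of per-class true positives equals the trace
        assert sum(cm.tp(i) for i in range(5)) == np.trace(cm.counts)
        assert acc == pytest.approx(100.0 * np.trace(cm.counts) / cm.total)
    with pytest.raises(VinesegError):
        accuracy_and_error(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


def test_metrics_permutation_equivariant(rng):
    truth = rng.integers(0, 5, size=(20, 20))
    pred = rng.integers(0, 5, size=(20, 20))
    perm = rng.permutation(5)
    cm = confusion(_lm(pred), _lm(truth))
    cm_p = confusion(_lm(perm[pred]), _lm(perm[truth]))
    for i in range(5):
        assert tp_rate(cm, i) == pytest.approx(tp_rate(cm_p, perm[i]))
        assert fp_rate(cm, i) == pytest.approx(fp_rate(cm_p, perm[i]))


def test_roc_points():
    rep = MetricsReport(
        scene_id="s",
        tp_rate={n: 100.0 for n in CLASS_NAMES},
        fp_rate={n: 0.0 for n in CLASS_NAMES},
        precision={n: 100.0 for n in CLASS_NAMES},
        accuracy=100.0,
        error_rate=0.0,
    )
    pts = roc_points([rep])
    assert len(pts) == 5
    assert all(p[2] == 0.0 and p[3] == 100.0 for p in pts)  # perfect corner
    rep2 = MetricsReport(
        scene_id="s2",
        tp_rate={n: (None if n == "BRANCH" else 50.0) for n in CLASS_NAMES},
        fp_rate={n: 10.0 for n in CLASS_NAMES},
        precision={}, accuracy=50.0, error_rate=50.0,
    )
    assert len(roc_points([rep, rep2])) == 9  # undefined entry skipped


def test_round_half_away():
    assert round_half_away(75.75) == 75.8
    assert round_half_away(11.25) == 11.3
    assert round_half_away(-11.25) == -11.3
    assert round_half_away(2.249) == 2.2


def test_aggregate_trivial_cases():
    reps = field_study.sequential_reports()
    single = aggregate_scenes(reps[:1])
    assert single.mean_accuracy == reps[0].accuracy
    assert single.mean_precision["FRUIT"] == reps[0].precision["FRUIT"]
    constant = aggregate_scenes([reps[0]] * 6)
    assert constant.mean_accuracy == reps[0].accuracy


def test_aggregate_mixed_class_sets_rejected():
    reps = field_study.sequential_reports()
    broken = MetricsReport(scene_id="x", precision={"FRUIT": 1.0},
                           accuracy=1.0, error_rate=99.0)
    with pytest.raises(VinesegError):
        aggregate_scenes([reps[0], broken])


def test_field_study_aggregates_reproduce_published_means():
    """Cross-scene means of the published six-scene tables."""
    base = aggregate_scenes(field_study.rgb_baseline_reports())
    summary = aggregate_scenes(field_study.sequential_reports(), baseline=base)
    assert summary.mean_precision == {
        "FRUIT": 89.7, "STEM": 57.2, "LEAF": 87.6, "BRANCH": 5.4, "BACKGROUND": 89.2,
    }
    assert summary.mean_accuracy == 75.8
    assert summary.mean_tp_rate["FRUIT"] == 68.3
    assert summary.mean_tp_rate["STEM"] == 82.8
    assert summary.mean_tp_rate["LEAF"] == 82.0
    assert summary.mean_tp_rate["BRANCH"] == 24.3
    assert summary.mean_fp_rate["BRANCH"] == 11.3
    assert summary.mean_fp_rate["FRUIT"] == 1.1
    assert base.mean_precision["FRUIT"] == 72.5
    assert base.mean_precision["STEM"] == 9.8
    assert base.mean_precision["BRANCH"] == 2.9
    assert base.mean_precision["BACKGROUND"] == 66.6
    assert base.mean_accuracy == 35.1
    assert summary.improvement_points["FRUIT"] == 17.2
    assert summary.improvement_points["BRANCH"] == 2.5
    assert summary.improvement_points["BACKGROUND"] == 22.6
    assert summary.accuracy_ratio == 2.2
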