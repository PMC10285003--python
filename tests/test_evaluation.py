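"""Evaluation protocols: top-p rejection, AUROC/AP oracles, MAE curves."""

import numpy as np
import pytest

import octood as o
from octood.corruptions import round_half_up
from octood.evaluation import EvalCurve


def _pairwise_auroc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair counting."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _sweep_ap(scores, labels):
    """Independent oracle: step-wise precision-recall area by rank sweep."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    prev_r, ap = 0.0, 0.0
    for p_i, r_i in zip(precision, recall):
        ap += p_i * (r_i - prev_r)
        prev_r = r_i
    return ap


def test_topp_reject_examples():
    assert o.topp_reject(np.arange(10.0), 0.0).size == 0
    rejected = o.topp_reject(np.arange(1.0, 11.0), 0.3)
    assert set(rejected) == {9, 8, 7}
    labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 0])
    rejected = o.topp_reject(labels.astype(float), labels.mean())
    assert set(rejected) == set(np.flatnonzero(labels))


def test_topp_count_is_round_half_up():
    scores = np.random.default_rng(0).random(7)
    for p in (0.1, 0.5, 0.25, 0.49, 0.9):
        assert o.topp_reject(scores, p).size == round_half_up(p * 7)


def test_detection_metrics_against_bruteforce():
    rng = np.random.default_rng(0)
    for n in (20, 100, 200):
        scores = rng.standard_normal(n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = o.detection_metrics(scores, labels)
        assert res.auroc == pytest.approx(_pairwise_auroc(scores, labels),
                                          abs=1e-12)
        assert res.average_precision == pytest.approx(
            _sweep_ap(scores, labels), abs=1e-12)


def test_detection_metrics_toy_and_perfect():
    res = o.detection_metrics(np.array([0.1, 0.4, 0.35, 0.8]),
                              np.array([0, 0, 1, 1]))
    assert res.auroc == pytest.approx(0.75)
    sep = o.detection_metrics(np.array([0.0, 0.1, 0.9, 1.0]),
                              np.array([0, 0, 1, 1]))
    assert sep.auroc == 1.0 and sep.average_precision == 1.0


def test_detection_metrics_permutation_null():
    rng = np.random.default_rng(1)
    scores = rng.standard_normal(5000)
    labels = rng.permutation(np.repeat([0, 1], 2500))
    assert abs(o.detection_metrics(scores, labels).auroc - 0.5) < 0.02


def test_detection_metrics_single_class_error():
    with pytest.raises(ValueError):
        o.detection_metrics(np.arange(4.0), np.zeros(4, dtype=int))


def test_mae_unit_identity():
    curve = EvalCurve(method="x", p_grid=np.array([0.0, 0.5]),
                      mae_px=np.array([1.25, 2.0]),
                      n_retained=np.array([10, 5]))
    np.testing.assert_allclose(curve.mae_um, 3.7 * curve.mae_px)
    frame = curve.to_frame()
    assert list(frame.columns) == ["method", "p", "mae_px", "mae_um",
                                   "n_retained"]


def test_unseen_types_for_supervised():
    assert set(o.SUPERVISED_UNSEEN_TYPES) == {"stripes", "rectangle", "zoom",
                                              "contrast"}
    assert set(o.SUPERVISED_UNSEEN_TYPES) | set(o.SUPERVISED_TRAINING_TYPES) \
        == set(o.CORRUPTION_TYPES)


def test_rejection_curve_retains_expected_counts(retina_model, clean_test):
    mscans, ilm = clean_test
    X, y = mscans[:60], ilm[:60]
    curve = o.rejection_experiment(X, y, o.oracle_scorer, retina_model,
                                   p_grid=[0.0, 0.3, 0.5], seed=3)
    np.testing.assert_array_equal(curve.n_retained, [60, 42, 30])
    assert np.isfinite(curve.mae_px).all()


def test_per_corruption_report_shape(mahaad_detector, clean_test):
    table = o.per_corruption_report(clean_test[0][:60],
                                    {"mahaad": mahaad_detector}, p=0.5, seed=5)
    assert set(table["ctype"]) == set(o.CORRUPTION_TYPES)
    assert len(table) == 8
    assert table["auroc"].between(0, 1).all()
    assert table.loc[table.ctype == "zoom", "unseen_by_supervised"].all()
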