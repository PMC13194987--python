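"""Metric oracles (concordance AUC, hand-ranked Friedman), confusion-matrix
identities, stratification, and the evaluation designs on tiny cohorts."""

import numpy as np
import pytest
from scipy import stats

from smokesense.evaluation import (EvalReport, FriedmanResult, _report,
                                   confusion_counts, friedman_test,
                                   phase_transfer_eval, roc_auc,
                                   within_subject_eval)

from conftest import make_dataset


# ----------------------------------------------------------------------
# ROC / AUC

def concordance_probability(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force pairwise concordance: P(score_pos > score_neg) with ties
    counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))


def test_auc_equals_concordance_on_1000_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(4, 30))
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        # discretise so score ties occur
        scores = np.round(rng.random(n), 1)
        _, _, auc = roc_auc(scores, labels)
        assert abs(auc - concordance_probability(scores, labels)) < 1e-12


def test_auc_extremes():
    labels = np.array([0, 0, 1, 1])
    _, _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels)
    assert auc == 1.0
    _, _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels)
    assert auc == 0.0
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, 4000)
    _, _, auc = roc_auc(rng.random(4000), labels)
    assert 0.45 < auc < 0.55


def test_roc_monotone_in_both_axes():
    rng = np.random.default_rng(2)
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    fpr, tpr, _ = roc_auc(scores, labels)
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


# ----------------------------------------------------------------------
# confusion matrix / predictive values

def test_confusion_identities_on_random_predictions():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(2, 60))
        y = rng.integers(0, 2, n)
        y_hat = rng.integers(0, 2, n)
        tp, fp, tn, fn = confusion_counts(y, y_hat)
        assert tp + fp + tn + fn == n
        acc = (tp + tn) / n
        assert np.isclose(acc, (y == y_hat).mean())


def test_predictive_values_undefined_reported_as_none():
    y = np.array([1, 1, 0, 0])
    y_hat = np.zeros(4, dtype=int)    # no positive predictions
    ds = make_dataset(np.zeros((4, 25, 11)), y)
    rep = _report("within_subject", "1dcnn", "ACC", ds,
                  np.full(4, 0.1), y_hat, with_roc=False)
    assert rep.ppv is None
    assert rep.npv == 0.5
    assert rep.accuracy == 0.5


# ----------------------------------------------------------------------
# Friedman test

def test_friedman_hand_computed_toy_grid():
    """4 blocks x 3 treatments with tie-free ranks computed by hand:
    mean ranks (1.25, 2, 2.75) give Q = 4.5, df = 2, p = exp(-2.25)."""
    grid = np.array([[1, 2, 3],
                     [2, 1, 3],
                     [1, 2, 3],
                     [1, 3, 2]], dtype=float)
    res = friedman_test(grid)
    assert np.isclose(res.Q, 4.5)
    assert res.df == 2
    assert np.isclose(res.p, np.exp(-2.25), atol=1e-12)


def test_friedman_identical_columns_gives_zero_statistic():
    grid = np.tile(np.array([[0.7, 0.7, 0.7, 0.7]]), (5, 1))
    res = friedman_test(grid)
    assert res.Q == 0.0 and res.p == 1.0
    assert not res.significant_05 and not res.significant_01


def test_friedman_matches_scipy_on_tie_free_grids():
    rng = np.random.default_rng(4)
    for _ in range(10):
        grid = rng.standard_normal((8, 4))
        ours = friedman_test(grid)
        q, p = stats.friedmanchisquare(*grid.T)
        assert np.isclose(ours.Q, q, atol=1e-10)
        assert np.isclose(ours.p, p, atol=1e-10)


def test_friedman_p_decreases_with_effect_strength():
    base = np.random.default_rng(5).standard_normal((6, 3)) * 0.01
    weak = friedman_test(base + np.array([0.0, 0.005, 0.01]))
    strong = friedman_test(base + np.array([0.0, 1.0, 2.0]))
    assert strong.Q > weak.Q
    assert strong.p < weak.p


def test_friedman_rejects_degenerate_grid():
    with pytest.raises(ValueError):
        friedman_test(np.ones((1, 3)))
    with pytest.raises(ValueError):
        friedman_test(np.ones((3, 1)))


# ----------------------------------------------------------------------
# stratified reporting

def test_strata_weighted_mean_recovers_overall_accuracy():
    rng = np.random.default_rng(6)
    n = 60
    y = rng.integers(0, 2, n)
    kinds = np.where(y == 1,
                     rng.choice(["lapse", "craving"], n), "none")
    levels = np.where(kinds == "craving", rng.integers(1, 6, n),
                      np.nan).astype(float)
    ds = make_dataset(rng.standard_normal((n, 25, 11)), y, kinds=kinds,
                      levels=levels, phase=2)
    y_hat = rng.integers(0, 2, n)
    rep = _report("phase_transfer", "1dcnn", "ACC", ds,
                  rng.random(n), y_hat, with_roc=False)
    sizes = ds.meta.groupby("event_kind").size()
    weighted = sum(rep.strata_by_kind[k] * sizes[k] for k in sizes.index) / n
    assert np.isclose(weighted, rep.accuracy)
    hours = ds.meta.groupby("hour_of_day").size()
    weighted_h = sum(rep.strata_by_hour[h] * hours[h] for h in hours.index) / n
    assert np.isclose(weighted_h, rep.accuracy)


def test_report_confusion_counts_sum_to_test_size():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, 30)
    ds = make_dataset(rng.standard_normal((30, 25, 11)), y)
    rep = _report("within_subject", "lstm", "ACC", ds, rng.random(30),
                  rng.integers(0, 2, 30), with_roc=False)
    assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n_test == 30


# ----------------------------------------------------------------------
# evaluation designs on a tiny cohort (small model for speed)

def test_phase_transfer_skips_silent_participant(tiny_bundle):
    import dataclasses
    from smokesense.io import EventLog
    silent = dataclasses.replace(tiny_bundle, phase2_events=EventLog())
    with pytest.warns(UserWarning, match="no Phase-2"):
        assert phase_transfer_eval(silent, "1dcnn", "ACC", 0) is None


def test_phase_transfer_populates_kind_strata(tiny_bundle):
    from smokesense.nn.models import small_config
    rep = phase_transfer_eval(tiny_bundle, "1dcnn-bilstm", "ACC-GYR-MAG", 0,
                              small_config(epochs=8))
    assert rep.design == "phase_transfer"
    assert {"none"} < set(rep.strata_by_kind)
    assert set(rep.strata_by_kind) <= {"none", "lapse", "craving"}
    assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n_test


def test_within_subject_report_structure(tiny_bundle):
    from smokesense.nn.models import small_config
    rep = within_subject_eval(tiny_bundle, "1dcnn", "ACC", seed=1,
                              model_config=small_config(epochs=8))
    assert rep.design == "within_subject"
    assert 0.0 <= rep.accuracy <= 1.0
    assert rep.participant_id == "p01"
    assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n_test > 0
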