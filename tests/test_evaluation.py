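"""Metric formulas, macro-averaging, and split-plan protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boldwct import (
    ConfusionMatrix,
    binary_metrics,
    f_score_from,
    kfold_plan,
    leave_one_site_out,
    macro_average,
    make_holdout_split,
)
from boldwct.evaluation import EvaluationError, aggregate_entries, format_mean_sd


# ----------------------------------------------------------------- metrics

def test_binary_metrics_hand_arithmetic():
    m = binary_metrics(tp=3, fp=1, fn=2, tn=4)
    assert m.precision == pytest.approx(75.0)
    assert m.sensitivity == pytest.approx(60.0)
    assert m.specificity == pytest.approx(80.0)
    assert m.accuracy == pytest.approx(70.0)
    assert round(m.f_score, 1) == 66.7


def test_perfect_predictions_all_hundred():
    m = binary_metrics(tp=10, fp=0, fn=0, tn=10)
    assert all(v == 100.0 for v in m.as_dict().values())


def test_f_score_harmonic_mean_of_reported_row():
    # precision 86.5%, sensitivity 88.3% -> F-score 87.4%
    assert round(f_score_from(86.5, 88.3), 1) == 87.4


def test_zero_denominator_reported_as_zero_with_flag():
    m = binary_metrics(tp=0, fp=0, fn=3, tn=5)
    assert m.precision == 0.0
    assert "precision" in m.undefined and "f_score" in m.undefined


def test_empty_confusion_rejected():
    with pytest.raises(EvaluationError):
        binary_metrics(0, 0, 0, 0)
    with pytest.raises(EvaluationError):
        binary_metrics(-1, 2, 3, 4)


@settings(derandomize=True, max_examples=50)
@given(st.tuples(*(st.integers(0, 50) for _ in range(4))).filter(lambda t: sum(t) > 0))
def test_f_score_identity_holds_for_any_confusion(counts):
    """Reported F equals the harmonic mean of reported P and S."""
    m = binary_metrics(*counts)
    assert m.f_score == pytest.approx(f_score_from(m.precision, m.sensitivity), abs=1e-9)


# ----------------------------------------------------------- macro average

def test_macro_equals_brute_force_one_vs_rest():
    counts = np.array([[8, 1, 1], [2, 7, 1], [0, 2, 8]])
    cm = ConfusionMatrix(counts, ["a", "b", "c"])
    report = macro_average(cm)
    total = counts.sum()
    entries = []
    for i in range(3):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        tn = total - tp - fp - fn
        entries.append(binary_metrics(tp, fp, fn, tn))
    for name in ("precision", "sensitivity", "specificity", "accuracy", "f_score"):
        expected = np.mean([getattr(e, name) for e in entries])
        assert getattr(report.macro, name) == pytest.approx(expected)


def test_binary_macro_accuracy_equals_pooled_accuracy():
    cm = ConfusionMatrix(np.array([[40, 10], [10, 40]]), ["ASD", "NC"])
    report = macro_average(cm)
    assert report.macro.accuracy == pytest.approx(80.0)
    assert report.per_class["ASD"].accuracy == pytest.approx(80.0)


def test_diagonal_confusion_scores_hundred():
    report = macro_average(ConfusionMatrix(np.diag([5, 6, 7, 8]), list("abcd")))
    assert all(v == 100.0 for v in report.macro.as_dict().values())


def test_zero_support_class_flagged_and_excludable():
    counts = np.array([[5, 0], [0, 0]])
    cm = ConfusionMatrix(counts, ["pos", "none"])
    by_zero = macro_average(cm, zero_support="zero")
    assert "zero_support" in by_zero.per_class["none"].undefined
    by_excl = macro_average(cm, zero_support="exclude")
    assert by_excl.macro.accuracy == pytest.approx(100.0)


def test_confusion_from_predictions_total():
    cm = ConfusionMatrix.from_predictions([0, 1, 1, 0], [0, 1, 0, 0], ["x", "y"])
    assert cm.total == 4
    assert cm.counts[1, 0] == 1


# ----------------------------------------------------------------- holdout

def test_holdout_sizes_700_150_150():
    plan = make_holdout_split(np.repeat([0, 1], 500), seed=0)
    assert (len(plan.train), len(plan.val), len(plan.test)) == (700, 150, 150)
    joined = np.sort(np.concatenate([plan.train, plan.val, plan.test]))
    np.testing.assert_array_equal(joined, np.arange(1000))


def test_holdout_is_stratified_within_one():
    labels = np.array([0] * 70 + [1] * 30)
    plan = make_holdout_split(labels, seed=1)
    for part in (plan.train, plan.val, plan.test):
        frac = labels[part].mean()
        assert abs(frac - 0.3) <= 1.5 / len(part)


def test_subject_unit_split_has_no_leakage():
    subjects = np.repeat([f"s{i}" for i in range(20)], 5)
    labels = np.repeat(np.tile([0, 1], 10), 5)
    plan = make_holdout_split(labels, unit_groups=subjects, seed=2)
    sets = [set(subjects[p]) for p in (plan.train, plan.val, plan.test)]
    assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])


def test_holdout_seed_reproducible():
    labels = np.repeat([0, 1], 50)
    a = make_holdout_split(labels, seed=5)
    b = make_holdout_split(labels, seed=5)
    np.testing.assert_array_equal(a.train, b.train)
    np.testing.assert_array_equal(a.test, b.test)


def test_holdout_bad_ratios_rejected():
    with pytest.raises(EvaluationError, match="ratios"):
        make_holdout_split([0, 1] * 10, ratios=(0.7, 0.2, 0.2))


# ------------------------------------------------------------------ k-fold

def test_kfold_disjoint_covering_folds():
    labels = np.repeat([0, 1], 50)
    plan = kfold_plan(labels, k=10, seed=0)
    assert len(plan.folds) == 10
    assert all(len(f) == 10 for f in plan.folds)
    joined = np.sort(np.concatenate(plan.folds))
    np.testing.assert_array_equal(joined, np.arange(100))
    # stratified: each fold carries both classes equally
    assert all(labels[f].mean() == 0.5 for f in plan.folds)


def test_kfold_infeasible_k_rejected():
    with pytest.raises(EvaluationError):
        kfold_plan([0, 1, 0, 1], k=10)
    with pytest.raises(EvaluationError, match="fewer than k"):
        kfold_plan([0] * 20 + [1] * 3, k=5)


# -------------------------------------------------------------------- LOSO

def _toy_sites():
    # 8 sites; only 4 carry both classes (mirrors a multi-site binary cohort)
    sites, labels = [], []
    for site, classes in [
        ("NYU", "AN"), ("SBL", "AN"), ("SDSU", "AN"), ("Yale", "AN"),
        ("Trinity", "A"), ("USM", "A"), ("KKI", "A"), ("UM1", "N"),
    ]:
        for c in classes * 3:
            sites.append(site)
            labels.append(c)
    return np.array(sites), np.array(labels)


def test_loso_rounds_only_for_complete_sites():
    sites, labels = _toy_sites()
    plan = leave_one_site_out(sites, labels, required_classes=["A", "N"])
    names = [r[0] for r in plan.rounds]
    assert names == ["NYU", "SBL", "SDSU", "Yale"]
    for site, train_idx, test_idx in plan.rounds:
        assert set(sites[test_idx]) == {site}
        assert site not in set(sites[train_idx])
        assert len(train_idx) + len(test_idx) == len(sites)


def test_loso_two_site_toy():
    sites = np.array(["a"] * 4 + ["b"] * 4)
    labels = np.array([0, 1] * 4)
    plan = leave_one_site_out(sites, labels)
    assert len(plan.rounds) == 2


def test_loso_no_eligible_site_errors():
    with pytest.raises(EvaluationError):
        leave_one_site_out(["a", "a", "b", "b"], [0, 0, 1, 1])


# ------------------------------------------------------------- aggregation

def test_aggregate_mean_sd_layout():
    from boldwct import MetricEntry

    entries = {
        "NYU": MetricEntry(86.5, 88.3, 86.8, 87.5, 87.4),
        "SBL": MetricEntry(85.9, 87.6, 86.2, 86.9, 86.7),
    }
    frame = aggregate_entries(entries)
    assert list(frame.index) == ["NYU", "SBL", "mean", "sd"]
    assert frame.loc["mean", "accuracy"] == pytest.approx(87.2)
    text = format_mean_sd(frame)
    assert "±" in text["accuracy"]
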