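"""Metrics, leave-one-repetition-out ensembles, case-unit aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from uteroflow import (
    MetricsReport,
    aggregate_repetitions,
    build_ensembles,
    case_unit_predict,
    compute_metrics,
    rank_auc,
)
from uteroflow.evaluation import case_representative_scores


def make_records(scores_by_rep, case_id="c", image_type="P", fold=1):
    rows = []
    for rep, scores in scores_by_rep.items():
        for w, s in enumerate(scores):
            rows.append(
                dict(case_id=case_id, window_start=w, image_type=image_type,
                     fold=fold, repetition=rep, score=s)
            )
    return pd.DataFrame(rows)


class TestComputeMetrics:
    def test_balanced_accuracy_is_mean_of_sens_and_spec(self):
        report = MetricsReport(auc=0.835, sensitivity=0.879, specificity=0.583,
                               accuracy=0.754)
        assert report.balanced_accuracy == pytest.approx(0.731, abs=1e-12)

    def test_perfect_separation_gives_auc_one(self):
        truths = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        report = compute_metrics((scores >= 0.5).astype(int), truths, scores)
        assert report.auc == 1.0
        assert report.accuracy == 1.0

    def test_auc_matches_bruteforce_concordance(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.uniform(0, 1, 30), 1)  # rounding forces ties
        truths = rng.integers(0, 2, 30)
        while len(set(truths)) < 2:
            truths = rng.integers(0, 2, 30)
        pos = scores[truths == 1]
        neg = scores[truths == 0]
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        brute = concordant / (len(pos) * len(neg))
        assert rank_auc(scores, truths) == pytest.approx(brute, abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 50)
        truths = rng.integers(0, 2, 50)
        assert rank_auc(scores, truths) == pytest.approx(
            roc_auc_score(truths, scores), abs=1e-12
        )

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([1, 1], [1, 1], [0.8, 0.9])

    def test_confusion_matrix_arithmetic(self):
        preds = np.array([1, 1, 0, 0, 1, 0])
        truths = np.array([1, 0, 0, 1, 1, 0])
        scores = preds.astype(float)
        report = compute_metrics(preds, truths, scores)
        assert report.sensitivity == pytest.approx(2 / 3)
        assert report.specificity == pytest.approx(2 / 3)
        assert report.accuracy == pytest.approx(4 / 6)


class TestAggregateRepetitions:
    def test_identical_reports_have_zero_sd(self):
        r = MetricsReport(0.8, 0.7, 0.6, 0.65)
        summary = aggregate_repetitions([r, r, r])
        assert all(m["sd"] == pytest.approx(0.0, abs=1e-12) for m in summary.values())

    def test_two_point_sample_sd(self):
        a = MetricsReport(0.5, 0.5, 0.5, 0.6)
        b = MetricsReport(0.5, 0.5, 0.5, 0.8)
        summary = aggregate_repetitions([a, b])
        assert summary["accuracy"]["mean"] == pytest.approx(0.7)
        assert summary["accuracy"]["sd"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_single_report_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_repetitions([MetricsReport(0.5, 0.5, 0.5, 0.5)])


class TestBuildEnsembles:
    def test_mean_of_constant_repetitions(self):
        records = make_records({r: [0.3, 0.3] for r in range(1, 13)})
        ens = build_ensembles(records)
        assert np.allclose(ens["score"], 0.3)
        assert sorted(ens["left_out_repetition"].unique()) == list(range(1, 13))

    def test_leave_one_out_matches_hand_arithmetic(self):
        values = {r: [r / 10.0] for r in range(1, 13)}  # 0.1 .. 1.2
        ens = build_ensembles(make_records(values))
        for rep in range(1, 13):
            expected = np.mean([r / 10.0 for r in range(1, 13) if r != rep])
            got = ens.loc[ens["left_out_repetition"] == rep, "score"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_member_order_invariance(self):
        records = make_records({r: [0.1 * r, 0.05 * r] for r in range(1, 7)})
        shuffled = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = build_ensembles(records).sort_values(
            ["left_out_repetition", "window_start"]).reset_index(drop=True)
        b = build_ensembles(shuffled).sort_values(
            ["left_out_repetition", "window_start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_repetition_coverage_rejected(self):
        records = make_records({1: [0.5], 2: [0.5]})
        # repetition 2 lacks image window_start=1
        extra = make_records({1: [0.5, 0.6]})
        broken = pd.concat([records, extra.iloc[1:]], ignore_index=True)
        with pytest.raises(ValueError, match="repetition"):
            build_ensembles(broken)

    def test_ensembling_reduces_across_set_variance(self):
        rng = np.random.default_rng(2)
        records = make_records(
            {r: rng.uniform(0, 1, 5).tolist() for r in range(1, 13)}
        )
        ens = build_ensembles(records)
        single_sd = records.groupby("window_start")["score"].std(ddof=1)
        ens_sd = ens.groupby("window_start")["score"].std(ddof=1)
        assert (ens_sd <= single_sd + 1e-12).all()


class TestCaseUnitPredict:
    def test_saturated_scores(self):
        scores = {w: 1.0 for w in range(27)}
        rep = case_unit_predict(scores, frames_per_case=30)
        assert rep.total_score == pytest.approx(17.0)
        assert rep.predicted == 1

    def test_twenty_frame_case_has_one_window(self):
        scores = {w: 0.2 for w in range(17)}
        rep = case_unit_predict(scores, frames_per_case=20)
        assert rep.best_window_start == 0
        assert rep.total_score == pytest.approx(0.2 * 17)
        assert rep.predicted == 0

    def test_argmax_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        scores = {w: float(rng.uniform(0, 1)) for w in range(27)}
        rep = case_unit_predict(scores, frames_per_case=30, n_windows=10)
        brute = max(
            range(10), key=lambda s: sum(scores[i] for i in range(s, s + 17))
        )
        assert rep.best_window_start == brute

    def test_insufficient_frames_rejected(self):
        with pytest.raises(ValueError, match="20"):
            case_unit_predict({w: 0.5 for w in range(10)}, frames_per_case=13)

    def test_invariant_to_submaximal_windows(self):
        rng = np.random.default_rng(4)
        scores = {w: float(rng.uniform(0, 0.3)) for w in range(27)}
        scores[3] = 5.0  # window 3 dominates regardless of others
        few = case_unit_predict(scores, frames_per_case=30, n_windows=4)
        many = case_unit_predict(scores, frames_per_case=30, n_windows=10)
        assert few.best_window_start == many.best_window_start
        assert few.total_score == pytest.approx(many.total_score)


def test_case_representative_scores_shape():
    rng = np.random.default_rng(5)
    frames = {
        rep: rng.uniform(0, 1, 27).tolist() for rep in range(1, 4)
    }
    records = pd.concat(
        [make_records(frames, case_id=cid) for cid in ("a", "b")],
        ignore_index=True,
    )
    out = case_representative_scores(records, frames_per_case=30)
    assert set(out["case_id"]) == {"a", "b"}
    assert len(out) == 2 * 3
    assert out["score"].between(0, 1).all()
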