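"""Clinical encoding, imputation, descriptors, split and Random Forest."""

import numpy as np
import pandas as pd
import pytest

from uteroflow import (
    ClinicalRecord,
    SimulationConfig,
    build_feature_matrix,
    clinical_frame,
    encode_clinical,
    evaluate_model,
    fit_random_forest,
    generate_cohort,
    impute_median,
    read_clinical_csv,
    run_fusion,
    split_cohort,
    summarize_scores,
    write_clinical_csv,
)
from uteroflow.fusion import BASELINE_VARS, DESCRIPTOR_VARS

from conftest import TINY_STACK


def make_record(case_id="p1", truth=1, **overrides):
    base = dict(
        case_id=case_id, age=36.0, gravidity=1, parity=0,
        transfers_before=4, transfers_after=2,
        leiomyoma=0, adenomyosis=0, ovarian_endometrioma=0,
        endometrial_polyp=0, uterine_anomaly=0, oviductal_anomaly=0,
        hysteroscopy_abnormal=0, cd138_positive=0, non_lactobacillus=0,
        mycoplasma_positive=0, truth=truth,
    )
    base.update(overrides)
    return ClinicalRecord(**base)


class TestEncodeClinical:
    def test_all_normal_record_has_zero_composites(self):
        _, comps = encode_clinical(make_record())
        assert comps.pathology_count == 0
        assert comps.inflammation_score == 0

    def test_pathology_count_sums_lesions(self):
        _, comps = encode_clinical(
            make_record(leiomyoma=1, endometrial_polyp=1)
        )
        assert comps.pathology_count == 2

    def test_missing_indicator_becomes_nan(self):
        series, comps = encode_clinical(make_record(non_lactobacillus=None,
                                                    cd138_positive=1))
        assert np.isnan(series["non_lactobacillus"])
        assert comps.inflammation_score == 1  # sum over observed values

    def test_non_binary_indicator_named_in_error(self):
        with pytest.raises(ValueError, match="leiomyoma"):
            make_record(leiomyoma=2)


class TestImputeMedian:
    def test_complete_matrix_unchanged(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = impute_median(frame, np.array([True, True, False]))
        pd.testing.assert_frame_equal(out, frame)

    def test_median_of_odd_training_set(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan]})
        out = impute_median(frame, np.array([True, True, True, False]))
        assert out.loc[3, "a"] == 2.0

    def test_validation_rows_never_inform_imputation(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"a": rng.uniform(0, 1, 10)})
        frame.loc[7, "a"] = np.nan
        mask = np.array([True] * 5 + [False] * 5)
        baseline = impute_median(frame, mask)
        permuted = frame.copy()
        permuted.loc[~mask & permuted["a"].notna(), "a"] = 99.0
        out = impute_median(permuted, mask)
        assert out.loc[7, "a"] == baseline.loc[7, "a"]

    def test_infinite_entries_treated_as_missing(self):
        frame = pd.DataFrame({"a": [1.0, np.inf, 3.0]})
        out = impute_median(frame, np.array([True, True, True]))
        assert out.loc[1, "a"] == 2.0

    def test_all_missing_training_column_rejected(self):
        frame = pd.DataFrame({"a": [np.nan, np.nan, 1.0]})
        with pytest.raises(ValueError, match="all-missing"):
            impute_median(frame, np.array([True, True, False]))


class TestSummarizeScores:
    def test_constant_vector(self):
        d = summarize_scores([0.4] * 12)
        assert d.score_mean == pytest.approx(0.4, abs=1e-12)
        assert d.score_median == 0.4
        assert d.score_range == d.score_iqr == 0.0
        assert d.score_std == pytest.approx(0.0, abs=1e-12)

    def test_matches_declared_quantile_rule(self):
        values = np.array([r / 12.0 for r in range(1, 13)])
        d = summarize_scores(values)
        srt = np.sort(values)

        def quantile(q):  # linear interpolation between order statistics
            pos = q * (len(srt) - 1)
            lo, frac = int(np.floor(pos)), pos % 1
            return srt[lo] * (1 - frac) + srt[min(lo + 1, len(srt) - 1)] * frac

        assert d.score_mean == pytest.approx(values.mean())
        assert d.score_std == pytest.approx(np.std(values, ddof=1))
        assert d.score_range == pytest.approx(values.max() - values.min())
        assert d.score_iqr == pytest.approx(quantile(0.75) - quantile(0.25))
        assert d.score_median == pytest.approx(quantile(0.5))

    def test_singleton_std_defined_as_zero(self):
        assert summarize_scores([0.7]).score_std == 0.0

    def test_descriptor_invariants(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = summarize_scores(rng.uniform(0, 1, 12))
            assert d.score_range >= d.score_iqr >= 0.0
            assert d.score_std >= 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_scores([])


class TestSplitCohort:
    def test_188_cases_split_131_57(self):
        ids = [f"case_{i:04d}" for i in range(188)]
        train, val = split_cohort(ids, seed=42)
        assert (len(train), len(val)) == (131, 57)

    def test_partitions_are_case_disjoint(self):
        ids = [f"c{i}" for i in range(50)]
        train, val = split_cohort(ids, seed=42)
        assert not set(train) & set(val)
        assert set(train) | set(val) == set(ids)

    def test_deterministic_at_fixed_seed(self):
        ids = [f"c{i}" for i in range(30)]
        assert split_cohort(ids, seed=42) == split_cohort(ids, seed=42)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            split_cohort(["only"])


@pytest.fixture(scope="module")
def cohort_clinical():
    config = SimulationConfig(n_cases=60, seed=23, **TINY_STACK)
    cases = generate_cohort(config)
    return clinical_frame(c.clinical for c in cases)


@pytest.fixture(scope="module")
def case_scores(cohort_clinical):
    rng = np.random.default_rng(7)
    rows = []
    for cid in cohort_clinical.index:
        truth = cohort_clinical.loc[cid, "truth"]
        center = 0.7 if truth == 1 else 0.35
        for rep in range(1, 13):
            rows.append(
                {"case_id": cid, "left_out_repetition": rep,
                 "score": float(np.clip(rng.normal(center, 0.05), 0, 1))}
            )
    return pd.DataFrame(rows)


class TestFeatureMatrix:
    def test_fused_matrix_has_22_predictors(self, cohort_clinical, case_scores):
        train_ids, _ = split_cohort(list(cohort_clinical.index), seed=42)
        X = build_feature_matrix(cohort_clinical, train_ids, case_scores)
        assert X.shape[1] == 22
        assert list(X.columns[-5:]) == DESCRIPTOR_VARS
        assert not X.isna().any().any()

    def test_clinical_only_matrix_has_17_predictors(self, cohort_clinical):
        train_ids, _ = split_cohort(list(cohort_clinical.index), seed=42)
        X = build_feature_matrix(cohort_clinical, train_ids)
        assert X.shape[1] == 17

    def test_composites_recomputed_from_imputed_indicators(
        self, cohort_clinical
    ):
        train_ids, _ = split_cohort(list(cohort_clinical.index), seed=42)
        X = build_feature_matrix(cohort_clinical, train_ids)
        from uteroflow.fusion import INFLAMMATION_VARS, PATHOLOGY_VARS

        np.testing.assert_allclose(
            X["pathology_count"], X[PATHOLOGY_VARS].sum(axis=1)
        )
        np.testing.assert_allclose(
            X["inflammation_score"], X[INFLAMMATION_VARS].sum(axis=1)
        )


class TestRandomForestProtocol:
    def test_single_configuration_grid_is_returned(self, cohort_clinical):
        train_ids, _ = split_cohort(list(cohort_clinical.index), seed=42)
        X = build_feature_matrix(cohort_clinical, train_ids)
        y = cohort_clinical["truth"].astype(int)
        grid = {"n_estimators": [50], "max_depth": [3]}
        clf = fit_random_forest(
            X.loc[train_ids], y.loc[train_ids].to_numpy(), train_ids, grid=grid
        )
        assert clf.n_estimators == 50 and clf.max_depth == 3

    def test_empty_grid_rejected(self, cohort_clinical):
        train_ids, _ = split_cohort(list(cohort_clinical.index), seed=42)
        X = build_feature_matrix(cohort_clinical, train_ids)
        with pytest.raises(ValueError, match="grid"):
            fit_random_forest(X, cohort_clinical["truth"], list(X.index),
                              grid={"n_estimators": []})

    def test_metrics_consistent_with_confusion_matrix(
        self, cohort_clinical, case_scores
    ):
        result = run_fusion(cohort_clinical, case_scores, seed=42,
                            grid={"n_estimators": [100]})
        report = result["report"]
        clf = result["classifier"]
        X = result["features"].loc[result["validation_ids"]]
        y = cohort_clinical.loc[result["validation_ids"], "truth"].to_numpy()
        proba = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
        preds = (proba >= 0.5).astype(int)
        tp = int(((preds == 1) & (y == 1)).sum())
        fn = int(((preds == 0) & (y == 1)).sum())
        tn = int(((preds == 0) & (y == 0)).sum())
        fp = int(((preds == 1) & (y == 0)).sum())
        assert report.sensitivity == pytest.approx(tp / (tp + fn))
        assert report.specificity == pytest.approx(tn / (tn + fp))
        assert report.accuracy == pytest.approx((tp + tn) / len(y))
        assert report.balanced_accuracy == pytest.approx(
            (report.sensitivity + report.specificity) / 2, abs=1e-15
        )

    def test_majority_class_classifier_zeroes_one_rate(self):
        class Majority:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.tile([0.9, 0.1], (len(X), 1))

        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        y = np.array([0, 1, 0, 1])
        report = evaluate_model(Majority(), X, y)
        assert report.sensitivity == 0.0

    def test_fused_model_beats_clinical_only_with_signal(
        self, cohort_clinical, case_scores
    ):
        grid = {"n_estimators": [100]}
        clinical = run_fusion(cohort_clinical, None, seed=42, grid=grid)
        fused = run_fusion(cohort_clinical, case_scores, seed=42, grid=grid)
        assert fused["report"].auc >= clinical["report"].auc


def test_clinical_csv_roundtrip(tmp_path):
    records = [
        make_record("p1", truth=1, non_lactobacillus=None),
        make_record("p2", truth=0, leiomyoma=1),
    ]
    path = tmp_path / "clinical.csv"
    write_clinical_csv(records, path)
    back = read_clinical_csv(path)
    assert back == records
    header = pd.read_csv(path).columns.tolist()
    assert header == ["case_id"] + BASELINE_VARS + ["truth"]
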