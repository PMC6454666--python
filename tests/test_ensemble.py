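"""Fitting, prediction, metrics and cross-validation of the ensemble."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from evidfuse import (
    EvaluationReport,
    EvidentialEnsembleClassifier,
    ScoreMatrix,
    accuracy,
    auc,
    cross_validate,
    reference_fold_metrics,
)
from evidfuse.calibration import adjust_to_half
from evidfuse.evidence import combine_all, decision_value, weighted_bpa
from evidfuse.simulate import ChannelConfig, GeneratorConfig, generate_cohort

from oracles import brute_auc


def small_cohort(n=300, seed=5):
    return generate_cohort(GeneratorConfig(n_patients=n, seed=seed))


class TestScoreMatrix:
    def test_rejects_missing_scores(self):
        df = pd.DataFrame({"m": [0.1, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            ScoreMatrix(df)

    def test_rejects_non_binary_labels(self):
        df = pd.DataFrame({"m": [0.1, 0.2]})
        with pytest.raises(ValueError, match="0/1"):
            ScoreMatrix(df, pd.Series([0, 2], index=df.index))

    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame({"m": [0.1, 0.2]}, index=[1, 1])
        with pytest.raises(ValueError, match="unique"):
            ScoreMatrix(df)


class TestFit:
    def test_weights_on_simplex_and_threshold_in_range(self):
        data = small_cohort()
        est = EvidentialEnsembleClassifier().fit(data.scores, data.labels.to_numpy())
        assert np.all(est.weights_ >= 0)
        assert est.weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < est.decision_threshold_ < 1.0
        # the integer channel got auto min-max bounds, probability ones did not
        assert est.calibrations_["GRACE"].normalization is not None
        assert est.calibrations_["SVM"].normalization is None

    def test_single_model_gets_weight_one(self):
        data = small_cohort()
        scores = data.scores[["SVM"]]
        est = EvidentialEnsembleClassifier().fit(scores, data.labels.to_numpy())
        assert est.weights_ == pytest.approx([1.0], abs=1e-12)

    def test_near_perfect_channel_dominates_noise_channel(self):
        config = GeneratorConfig(
            n_patients=600,
            seed=11,
            channels=(
                ChannelConfig("sharp", signal=6.0, loading=0.0, noise_scale=0.1),
                ChannelConfig("noise", signal=0.0, loading=0.0, noise_scale=1.0),
            ),
        )
        data = generate_cohort(config)
        est = EvidentialEnsembleClassifier().fit(data.scores, data.labels.to_numpy())
        w = dict(zip(est.model_ids_, est.weights_))
        assert w["sharp"] > w["noise"]
        assert w["sharp"] == max(est.weights_)

    def test_single_class_labels_rejected(self):
        data = small_cohort(n=50)
        with pytest.raises(ValueError, match="single-class"):
            EvidentialEnsembleClassifier().fit(
                data.scores, np.zeros(len(data.scores), dtype=int)
            )

    def test_constant_scores_rejected_naming_model(self):
        df = pd.DataFrame({"flat": np.full(20, 0.4), "ok": np.linspace(0, 1, 20)})
        y = np.tile([0, 1], 10)
        with pytest.raises(ValueError, match="flat"):
            EvidentialEnsembleClassifier().fit(df, y)

    def test_refit_is_idempotent(self):
        data = small_cohort()
        y = data.labels.to_numpy()
        a = EvidentialEnsembleClassifier().fit(data.scores, y)
        b = EvidentialEnsembleClassifier().fit(data.scores, y)
        assert a.weights_ == pytest.approx(b.weights_, abs=0)
        assert a.decision_threshold_ == b.decision_threshold_
        assert {m: a.calibrations_[m].raw_threshold for m in a.model_ids_} == {
            m: b.calibrations_[m].raw_threshold for m in b.model_ids_
        }

    def test_row_order_does_not_affect_parameters(self, rng):
        data = small_cohort()
        perm = rng.permutation(len(data.scores))
        shuffled = data.subset(perm)
        a = EvidentialEnsembleClassifier().fit(data.scores, data.labels.to_numpy())
        b = EvidentialEnsembleClassifier().fit(
            shuffled.scores, shuffled.labels.to_numpy()
        )
        assert a.weights_ == pytest.approx(b.weights_, abs=1e-12)
        assert a.decision_threshold_ == pytest.approx(b.decision_threshold_, abs=0)

    def test_sklearn_params_roundtrip(self):
        est = EvidentialEnsembleClassifier(entropy_direction="as-printed")
        assert est.get_params()["entropy_direction"] == "as-printed"
        est.set_params(entropy_direction="decision-given-attrs")
        assert est.entropy_direction == "decision-given-attrs"


class TestPredict:
    def test_equals_manual_composition(self, rng):
        data = small_cohort(n=120, seed=3)
        est = EvidentialEnsembleClassifier().fit(data.scores, data.labels.to_numpy())
        r = est.decision_function(data.scores)
        for i in rng.choice(len(data.scores), size=10, replace=False):
            bpas = []
            for mid, w in zip(est.model_ids_, est.weights_):
                cal = est.calibrations_[mid]
                a = adjust_to_half(cal.to_unit(data.scores.iloc[i][mid]), cal.unit_threshold)
                bpas.append(weighted_bpa(float(a), w))
            assert r[i] == pytest.approx(decision_value(combine_all(bpas)), abs=1e-12)

    def test_column_mismatch_rejected(self):
        data = small_cohort(n=60)
        est = EvidentialEnsembleClassifier().fit(data.scores, data.labels.to_numpy())
        with pytest.raises(ValueError, match="mismatch"):
            est.predict(data.scores[["SVM", "CART"]])

    def test_predict_consistent_with_decision_function(self):
        data = small_cohort(n=60)
        est = EvidentialEnsembleClassifier().fit(data.scores, data.labels.to_numpy())
        r = est.decision_function(data.scores)
        np.testing.assert_array_equal(
            est.predict(data.scores), (r > est.decision_threshold_).astype(int)
        )


class TestMetrics:
    def test_auc_trivial_cases(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_auc_matches_pair_counting_oracle_and_sklearn(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=15), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=15)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = auc(scores, labels)
            assert got == pytest.approx(brute_auc(list(scores), list(labels)), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            auc([0.1, 0.9], [1, 1])

    def test_accuracy_cases(self, example):
        assert accuracy([1, 0, 1], [1, 0, 1]) == 1.0
        assert accuracy([1, 0], [0, 1]) == 0.0
        # the example's predictions disagree with the outcomes for two patients
        assert accuracy(
            example.expected_predictions.to_numpy(),
            example.score_matrix.labels.to_numpy(),
        ) == pytest.approx(0.8)

    def test_accuracy_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            accuracy([1, 0], [1, 0, 1])


class TestEvaluationReport:
    def test_mean_and_sample_sd_reproduce_reference_rows(self):
        ref = reference_fold_metrics()
        report = EvaluationReport.from_fold_values(
            ref["ensemble"]["auc"], ref["ensemble"]["accuracy"]
        )
        s = report.summary
        assert s.loc["mean", "auc"] == pytest.approx(0.715, abs=5e-4)
        assert s.loc["mean", "accuracy"] == pytest.approx(0.694, abs=5e-4)
        # sample (n-1) convention distinguishes itself on the SVM column
        svm = EvaluationReport.from_fold_values(
            ref["SVM"]["auc"], ref["SVM"]["accuracy"]
        ).summary
        assert svm.loc["sd", "auc"] == pytest.approx(0.022, abs=5e-4)
        assert np.std(ref["SVM"]["auc"], ddof=0) != pytest.approx(0.022, abs=5e-4)


class TestCrossValidate:
    def test_same_seed_reproduces_report(self):
        data = small_cohort(n=240, seed=9)
        a = cross_validate(data, k=3, seed=4)
        b = cross_validate(data, k=3, seed=4)
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)

    def test_summary_matches_fold_values(self):
        data = small_cohort(n=240, seed=9)
        report = cross_validate(data, k=3, seed=4)
        s = report.summary
        assert s.loc["mean", "auc"] == pytest.approx(report.per_fold["auc"].mean())
        assert s.loc["sd", "accuracy"] == pytest.approx(
            report.per_fold["accuracy"].std(ddof=1)
        )

    def test_unlabelled_data_rejected(self):
        data = small_cohort(n=60)
        with pytest.raises(ValueError, match="label"):
            cross_validate(ScoreMatrix(data.scores), k=3, seed=0)
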