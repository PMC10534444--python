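"""assessment_eval: outcome convention, metric formulas, classifiers, pipeline."""

import math

import numpy as np
import pytest

import fallhic as fh

# The reported random-forest confusion pattern on a 300-clip test set:
# class sizes 90/84/82/44, errors No->Minor 2, Minor->No 2,
# Moderate->Minor 3, Moderate->Heavy 3.
RF_MATRIX = np.array([
    [88, 2, 0, 0],
    [2, 82, 0, 0],
    [0, 3, 76, 3],
    [0, 0, 0, 44],
])


class TestOutcomeCounts:
    def test_rf_pattern_counts(self):
        oc = fh.outcome_counts(fh.ConfusionMatrix4(RF_MATRIX))
        assert (oc.TP, oc.TN, oc.FP, oc.FN) == (202, 88, 2, 8)
        assert oc.total == 300

    def test_diagonal_matrix_has_no_errors(self):
        cm = fh.ConfusionMatrix4(np.diag([10, 20, 30, 40]))
        oc = fh.outcome_counts(cm)
        assert oc.FP == 0 and oc.FN == 0
        assert oc.TN == 10 and oc.TP == 90

    def test_all_no_injury_predicted_minor(self):
        cm = fh.ConfusionMatrix4(np.array([[0, 15, 0, 0]] + [[0] * 4] * 3))
        oc = fh.outcome_counts(cm)
        assert oc.TN == 0 and oc.FP == 15

    def test_total_is_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cm = fh.ConfusionMatrix4(rng.integers(0, 30, (4, 4)))
            assert fh.outcome_counts(cm).total == cm.total

    def test_accuracy_equals_trace_over_total(self):
        """The outcome convention makes TP + TN exactly the diagonal."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 30, (4, 4))
            cm = fh.ConfusionMatrix4(counts)
            if cm.total == 0:
                continue
            report = fh.compute_metrics(fh.outcome_counts(cm))
            assert report.accuracy == pytest.approx(
                np.trace(counts) / cm.total, abs=1e-12
            )


class TestComputeMetrics:
    def test_reproduces_published_rf_row(self):
        report = fh.compute_metrics(fh.OutcomeCounts(TP=202, FP=2, TN=88, FN=8))
        rounded = {k: fh.percent(v) for k, v in report.as_dict().items()}
        assert rounded == {
            "sensitivity": 96.19, "specificity": 97.78,
            "accuracy": 96.67, "precision": 99.02, "f_score": 97.58,
        }

    def test_balanced_unit_counts_give_half(self):
        report = fh.compute_metrics(fh.OutcomeCounts(TP=1, FP=1, TN=1, FN=1))
        assert all(v == 0.5 for v in report.as_dict().values())

    def test_error_free_counts_give_ones(self):
        report = fh.compute_metrics(fh.OutcomeCounts(TP=5, FP=0, TN=7, FN=0))
        assert all(v == 1.0 for v in report.as_dict().values())

    def test_zero_denominators_are_marked_undefined(self):
        report = fh.compute_metrics(fh.OutcomeCounts(TP=0, FP=0, TN=3, FN=0))
        assert math.isnan(report.sensitivity)
        assert "sensitivity" in report.undefined
        assert "precision" in report.undefined
        assert report.specificity == 1.0

    @pytest.mark.parametrize("p, expected", [
        (0.123456, 12.35), (0.5, 50.0), (0.96665, 96.67), (0.999999, 100.0),
    ])
    def test_percent_rounds_half_away_to_two_decimals(self, p, expected):
        assert fh.percent(p) == expected


class TestClassifiers:
    def _toy_separable(self):
        rng = np.random.default_rng(2)
        X0 = rng.normal(0, 0.3, (30, 6))
        X1 = rng.normal(5, 0.3, (30, 6))
        X = np.vstack([X0, X1])
        y = np.array([0] * 30 + [1] * 30)
        return X, y

    def test_linear_svm_separates_toy_set(self):
        X, y = self._toy_separable()
        clf = fh.train_classifier(X, y, "svm_linear", seed=0)
        assert (clf.predict(X) == y).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 6))
        with pytest.raises(ValueError, match="single class"):
            fh.train_classifier(X, np.zeros(10, dtype=int), "rf")

    def test_unknown_kind_rejected(self):
        X, y = self._toy_separable()
        with pytest.raises(ValueError, match="kind"):
            fh.train_classifier(X, y, "boosted_stumps")

    def test_deterministic_given_seed(self):
        X, y = self._toy_separable()
        a = fh.train_classifier(X, y, "rf", seed=3).predict(X)
        b = fh.train_classifier(X, y, "rf", seed=3).predict(X)
        assert np.array_equal(a, b)

    def test_perfect_predictor_yields_identity_matrix(self):
        y = np.array([0, 1, 2, 3] * 5)
        X = y[:, None].astype(float) * np.ones((1, 6))

        class Oracle:
            def predict(self, X):
                return X[:, 0].astype(int)

        cm, report = fh.evaluate_classifier(Oracle(), X, y)
        assert np.array_equal(cm.counts, np.diag([5, 5, 5, 5]))
        assert all(v == 1.0 for v in report.as_dict().values())

    def test_constant_no_injury_predictor_has_zero_sensitivity(self):
        y = np.array([0, 1, 2, 3] * 5)
        X = np.ones((20, 6))

        class AlwaysNo:
            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        cm, report = fh.evaluate_classifier(AlwaysNo(), X, y)
        oc = fh.outcome_counts(cm)
        assert oc.TP == 0
        assert report.sensitivity == 0.0

    def test_empty_test_set_rejected(self):
        X, y = self._toy_separable()
        clf = fh.train_classifier(X, y, "rf")
        with pytest.raises(ValueError):
            fh.evaluate_classifier(clf, np.zeros((0, 6)), [])

    def test_threshold_mode_matches_severity_scale(self):
        feats = np.zeros((4, 6))
        feats[:, 1] = [100.0, 400.0, 850.0, 2000.0]  # the HIC column
        assert fh.hic_threshold_predict(feats).tolist() == [0, 1, 2, 3]


class TestFeatures:
    def test_features_from_analytic_trace(self):
        scenario = fh.FallScenario(drop_height=0.8, impact_omega=300.0,
                                   restitution=0.4)
        trace = fh.true_acceleration_trace(scenario)
        fv = fh.extract_features(trace)
        v = fh.impact_speed(0.8)
        expected_peak = 0.5 * 1.4 * v * 300.0 / 9.81
        assert fv.peak_accel_g == pytest.approx(expected_peak, rel=0.01)
        assert fv.hic == pytest.approx(fh.compute_hic(trace).hic)
        # free flight lasts v / g
        assert fv.fall_duration_s == pytest.approx(v / 9.81, rel=0.05)
        assert 0.0 < fv.bounce_ratio < 1.0


class TestAssess:
    def test_negligible_drop_is_no_alert(self, lifter_benchmark):
        scenario = fh.FallScenario(drop_height=0.02, impact_omega=200.0, seed=1)
        truth = fh.simulate_fall(scenario)
        seq = fh.project_to_camera(truth.pose3d, scenario.camera)
        report = fh.assess(seq, lifter_model=lifter_benchmark["model"])
        assert report["severity"] == 0
        assert report["alert"] is False

    def test_fully_occluded_clip_fails_in_repair_stage(self, lifter_benchmark):
        scenario = fh.FallScenario(drop_height=0.5, impact_omega=200.0, seed=2)
        truth = fh.simulate_fall(scenario)
        seq = fh.project_to_camera(truth.pose3d, scenario.camera)
        seq.conf[:] = 0.0
        seq.coords[:] = 0.0
        with pytest.raises(fh.StageError) as excinfo:
            fh.assess(seq, lifter_model=lifter_benchmark["model"])
        assert excinfo.value.stage == "repair"

    def test_supplied_3d_sequence_skips_lifting(self, tiny_dataset):
        clip = tiny_dataset.train[0]
        report = fh.assess(clip.occluded2d, pose3d=clip.truth.pose3d)
        assert report["quality"]["repair_mode"] == "linear"
        assert report["hic"] >= 0

    def test_report_is_json_serializable(self, tiny_dataset):
        import json
        clip = tiny_dataset.train[1]
        report = fh.assess(clip.occluded2d, pose3d=clip.truth.pose3d)
        json.dumps(report)
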