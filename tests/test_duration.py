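import math

import numpy as np
import pandas as pd
import pytest

from endosched.cohort import CohortSpec, generate_cohort
from endosched.domain import (ConfigurationError, InvalidPredictionError,
                              NoUsableDataError)
from endosched.duration import (FEATURE_GROUPS, DurationModel,
                                appointment_duration, backward_eliminate,
                                clean, cohort_frame, fit_predict,
                                make_regressor, split_frame)


class _Stub:
    """Regressor returning canned predictions; for metric arithmetic."""

    def __init__(self, values):
        self.values = np.asarray(values, float)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.values[: len(X)]


class TestClean:
    def test_masked_labels_are_dropped(self):
        """1332 raw rows with 79 missing durations leave 1253 usable ones."""
        cohort = generate_cohort(CohortSpec(n_patients=1332, seed=2))
        raw = cohort_frame(cohort)
        raw.loc[raw.index[:79], "actual_procedure_minutes"] = np.nan
        assert len(clean(raw)) == 1253

    def test_invalid_and_outlier_labels_dropped(self):
        cohort = generate_cohort(CohortSpec(n_patients=10, seed=2))
        raw = cohort_frame(cohort)
        raw.loc[0, "actual_procedure_minutes"] = 0.0     # invalid
        raw.loc[1, "actual_procedure_minutes"] = 120.0   # outlier
        assert len(clean(raw)) == 8

    def test_complete_data_is_identity(self):
        cohort = generate_cohort(CohortSpec(n_patients=25, seed=3))
        assert len(clean(cohort_frame(cohort))) == 25

    def test_all_dropped_raises(self):
        cohort = generate_cohort(CohortSpec(n_patients=3, seed=3))
        raw = cohort_frame(cohort)
        raw["actual_procedure_minutes"] = np.nan
        with pytest.raises(NoUsableDataError):
            clean(raw)

    def test_no_missing_values_after_encoding(self):
        cohort = generate_cohort(CohortSpec(n_patients=50, seed=4))
        fm = clean(cohort_frame(cohort))
        assert not fm.X.isna().any().any()


class TestAppointmentDuration:
    @pytest.mark.parametrize("predicted,mode,expected", [
        (16.2, "predictive", 31.2),
        (16.2, "fixed", 30.0),
        (55.0, "fixed", 30.0),
        (2.0, "predictive", 17.0),
    ])
    def test_buffer_and_fixed_modes(self, predicted, mode, expected):
        assert appointment_duration(predicted, mode) == pytest.approx(expected)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(InvalidPredictionError):
            appointment_duration(0.0, "predictive")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            appointment_duration(10.0, "slots")


class TestFitPredict:
    def test_metric_arithmetic(self):
        cohort = generate_cohort(CohortSpec(n_patients=12, seed=5))
        fm = clean(cohort_frame(cohort))
        train, test = split_frame(fm, test_fraction=2 / 12, seed=0)
        test.y.iloc[:] = [12.0, 26.0]
        _, mae, mse = fit_predict(lambda: _Stub([10.0, 20.0]), train, test)
        assert mae == pytest.approx(4.0)
        assert mse == pytest.approx(20.0)

    @pytest.mark.parametrize("name", ["linear", "gradient_boosted_trees"])
    def test_constant_labels_give_zero_error(self, name):
        cohort = generate_cohort(CohortSpec(n_patients=60, seed=6))
        fm = clean(cohort_frame(cohort))
        fm.y.iloc[:] = 25.0
        train, test = split_frame(fm, seed=0)
        _, mae, mse = fit_predict(name, train, test)
        assert mae == pytest.approx(0.0, abs=1e-6)
        assert mse == pytest.approx(0.0, abs=1e-9)

    def test_unknown_regressor_rejected(self):
        with pytest.raises(ConfigurationError):
            make_regressor("deep_transformer")

    def test_gbt_beats_mean_baseline(self, training_cohort):
        """With covariate signal, the model must beat predict-the-mean."""
        fm = clean(cohort_frame(training_cohort))
        train, test = split_frame(fm, seed=0)
        baseline_mae = np.mean(np.abs(test.y - train.y.mean()))
        _, mae, mse = fit_predict("gradient_boosted_trees", train, test)
        assert mae < baseline_mae
        assert mae <= np.std(np.concatenate([train.y, test.y]))

    @pytest.mark.parametrize("name", ["linear", "gradient_boosted_trees",
                                      "multilayer_perceptron"])
    def test_mae_never_exceeds_rmse(self, training_cohort, name):
        fm = clean(cohort_frame(training_cohort))
        train, test = split_frame(fm, seed=1)
        _, mae, mse = fit_predict(name, train, test)
        assert mae <= math.sqrt(mse) + 1e-12

    def test_predictions_floored_at_two_minutes(self, training_cohort):
        fm = clean(cohort_frame(training_cohort))
        train, test = split_frame(fm, seed=0)
        pred, _, _ = fit_predict("gradient_boosted_trees", train, test)
        assert (pred >= 2.0).all()


class TestBackwardElimination:
    def test_single_feature_trace(self):
        cohort = generate_cohort(CohortSpec(n_patients=80, seed=7))
        fm = clean(cohort_frame(cohort)).restrict(["procedure_type"])
        trace = backward_eliminate(fm, max_features=4, seed=0)
        assert trace.steps == []
        assert trace.selected_features == ("procedure_type",)

    def test_signal_feature_retained(self):
        """Procedure type dominates duration; selection must keep it."""
        cohort = generate_cohort(CohortSpec(n_patients=1500, seed=8))
        fm = clean(cohort_frame(cohort))
        trace = backward_eliminate(fm, max_features=4, seed=8)
        assert "procedure_type" in trace.selected_features
        assert len(trace.selected_features) <= 4
        # one fewer candidate per elimination round
        sizes = [len(fs) for fs, _ in trace.evaluated]
        assert sizes == list(range(len(FEATURE_GROUPS), 0, -1))

    def test_pure_noise_labels_show_no_real_improvement(self):
        """With shuffled labels no feature subset should beat the constant
        mean predictor by more than noise."""
        cohort = generate_cohort(CohortSpec(n_patients=800, seed=9))
        fm = clean(cohort_frame(cohort))
        rng = np.random.default_rng(0)
        fm.y.iloc[:] = rng.permutation(fm.y.to_numpy())
        trace = backward_eliminate(fm, max_features=4, seed=9)
        best_mae = min(mae for _, mae in trace.evaluated)
        mean_mae = np.mean(np.abs(fm.y - fm.y.mean()))
        assert best_mae > 0.95 * mean_mae

    def test_deterministic_under_fixed_seed(self):
        cohort = generate_cohort(CohortSpec(n_patients=400, seed=10))
        fm = clean(cohort_frame(cohort))
        t1 = backward_eliminate(fm, max_features=4, seed=3)
        t2 = backward_eliminate(fm, max_features=4, seed=3)
        assert t1.selected_features == t2.selected_features
        assert t1.evaluated == t2.evaluated


class TestDurationModel:
    def test_save_load_roundtrip(self, tmp_path, training_cohort):
        model = DurationModel(seed=0).fit(training_cohort[:400], select=False)
        preds = model.predict(training_cohort[400:450])
        path = tmp_path / "model.bin"
        model.save(path)
        again = DurationModel.load(path)
        assert np.allclose(again.predict(training_cohort[400:450]), preds)

    def test_annotate_fills_predictions(self, training_cohort):
        model = DurationModel(seed=0).fit(training_cohort[:400], select=False)
        target = [p for p in training_cohort[400:420]]
        model.annotate(target)
        assert all(p.predicted_procedure_minutes >= 2.0 for p in target)
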