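import numpy as np
import pandas as pd
import pytest

from stresspair import (
    NullDistribution,
    ValidationError,
    bootstrap_epe,
    confusion,
    empirical_p,
    fit_tsp,
    monte_carlo_null,
)
from conftest import make_fm


class ConstantModel:
    """Duck-typed predictor that always emits one class."""

    def __init__(self, features, level, levels):
        self.features = features
        self.level = level
        self.class_levels = levels

    def predict(self, fm):
        return pd.Series([self.level] * fm.n_samples, index=fm.data.index)


class TestConfusion:
    def test_counts_exact(self):
        cm = confusion(
            ["A", "A", "B", "B", "B"],
            ["A", "B", "B", "B", "A"],
        )
        assert cm.counts.tolist() == [[1, 1], [1, 2]]
        assert cm.total == 5
        assert cm.correct == 3

    def test_perfect_prediction_has_zero_error(self):
        cm = confusion(["A", "B"], ["A", "B"])
        assert cm.prediction_error == 0.0

    def test_error_equals_one_minus_recounted_accuracy(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        pred = model.predict(valid)
        cm = confusion(valid.labels, pred)
        direct = (pred.to_numpy() == valid.labels.to_numpy()).mean()
        assert cm.prediction_error == pytest.approx(1 - direct)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="unknown label"):
            confusion(["A", "B"], ["A", "C"], class_levels=("A", "B"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length mismatch"):
            confusion(["A"], ["A", "B"])


class TestMonteCarloNull:
    def test_constant_predictor_has_closed_form_error(self, train_valid):
        _, valid = train_valid
        model = ConstantModel(
            features=valid.feature_names[:2],
            level="Stress",
            levels=("NoStress", "Stress"),
        )
        null = monte_carlo_null(model, valid, n_iterations=200, seed=1)
        # always predicting Stress misclassifies exactly the 19 controls
        assert np.all(null.errors == 19 / 37)
        assert 18 / 37 <= null.mean_error <= 19 / 37

    def test_symmetric_balanced_template_centers_at_half(self):
        rng = np.random.default_rng(2)
        fm = make_fm(
            rng.uniform(0, 1, size=(40, 2)), labels=["A"] * 20 + ["B"] * 20
        )
        model = fit_tsp(fm)
        null = monte_carlo_null(model, fm, n_iterations=2000, seed=3)
        se = 0.5 / np.sqrt(40 * 2000)
        # balanced labels make the expectation exactly 1/2
        assert abs(null.mean_error - 0.5) < max(3 * se, 0.01)

    def test_deterministic_for_fixed_seed(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        a = monte_carlo_null(model, valid, n_iterations=50, seed=9)
        b = monte_carlo_null(model, valid, n_iterations=50, seed=9)
        np.testing.assert_array_equal(a.errors, b.errors)

    def test_degenerate_range_rejected(self):
        fm = make_fm([[1.0, 2.0], [1.0, 3.0]], labels=["A", "B"])
        model = ConstantModel(fm.feature_names, "A", ("A", "B"))
        with pytest.raises(ValidationError, match="degenerate range"):
            monte_carlo_null(model, fm, n_iterations=10, seed=0)

    def test_iteration_count_validated(self, train_valid):
        model = fit_tsp(train_valid[0])
        with pytest.raises(ValidationError, match="n_iterations"):
            monte_carlo_null(model, train_valid[1], n_iterations=0, seed=0)


class TestEmpiricalP:
    def test_no_lower_draw_gives_floor_p(self):
        null = NullDistribution(errors=np.full(10000, 0.5), seed=0)
        res = empirical_p(0.1, null)
        assert res.r == 0
        assert res.p == pytest.approx(1 / 10001)
        assert res.p < 0.0001

    def test_all_lower_draws_give_p_one(self):
        null = NullDistribution(errors=np.zeros(50), seed=0)
        assert empirical_p(0.9, null).p == 1.0

    def test_hand_built_null_formula(self):
        errors = np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9, 1.0])
        res = empirical_p(0.5, NullDistribution(errors=errors, seed=0))
        assert (res.r, res.N, res.p) == (4, 9, 5 / 10)

    def test_strictly_lower_counting(self):
        errors = np.array([0.5, 0.5, 0.4])
        assert empirical_p(0.5, NullDistribution(errors=errors, seed=0)).r == 1

    def test_out_of_range_epe_rejected(self):
        null = NullDistribution(errors=np.zeros(5), seed=0)
        with pytest.raises(ValidationError):
            empirical_p(1.5, null)


class TestBootstrap:
    def test_zero_error_model_degenerates_to_point(self, train_valid):
        _, valid = train_valid
        model = _PerfectModel(valid)
        boot = bootstrap_epe(model, valid, n_replicates=500, seed=4)
        assert boot.mean_error == 0.0
        assert (boot.ci_low, boot.ci_high) == (0.0, 0.0)

    def test_replicate_mean_tracks_observed_epe(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        for reps in (100, 1000, 10000):
            boot = bootstrap_epe(model, valid, n_replicates=reps, seed=5)
            se = boot.replicate_errors.std(ddof=1) / np.sqrt(reps)
            sampling_sd = boot.replicate_errors.std(ddof=1)
            # E[replicate] = observed EPE; the mean of R replicates sits
            # within ~3 resampling SDs of it
            assert abs(boot.mean_error - boot.observed_epe) < 3 * sampling_sd / np.sqrt(reps) + 1e-12

    def test_interval_ordering_and_range(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        boot = bootstrap_epe(model, valid, n_replicates=2000, seed=6)
        assert 0.0 <= boot.ci_low <= boot.ci_high <= 1.0

    def test_small_replicate_count_warns(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        with pytest.warns(UserWarning, match="small"):
            bootstrap_epe(model, valid, n_replicates=50, seed=7)

    def test_deterministic_for_fixed_seed(self, train_valid):
        train, valid = train_valid
        model = fit_tsp(train)
        a = bootstrap_epe(model, valid, n_replicates=300, seed=8)
        b = bootstrap_epe(model, valid, n_replicates=300, seed=8)
        np.testing.assert_array_equal(a.replicate_errors, b.replicate_errors)

    def test_bca_interval_matches_scipy_reference(self, train_valid):
        """Cross-check the hand-rolled BCa construction against scipy's
        independent implementation on the same misclassification vector."""
        from scipy.stats import bootstrap as scipy_bootstrap

        train, valid = train_valid
        model = fit_tsp(train)
        boot = bootstrap_epe(model, valid, n_replicates=9999, seed=9)
        miss = (model.predict(valid).to_numpy() != valid.labels.to_numpy()).astype(float)
        ref = scipy_bootstrap(
            (miss,),
            np.mean,
            method="BCa",
            n_resamples=9999,
            confidence_level=0.95,
            random_state=np.random.default_rng(10),
        )
        assert boot.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.03)
        assert boot.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.03)


class _PerfectModel:
    """Echoes the true labels back (zero prediction error)."""

    def __init__(self, fm):
        self.features = fm.feature_names[:2]
        self._labels = fm.labels

    def predict(self, fm):
        return self._labels.loc[fm.data.index]
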