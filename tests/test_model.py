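"""The model-development loop: SHAP importance, search, prediction, validation."""

import numpy as np
import pandas as pd
import pytest

from frailgait.agreement import RatingSet, weighted_kappa
from frailgait.model import (
    FL_MAX,
    FL_MIN,
    TrainingConfig,
    _clip_fl,
    _cv_rmse,
    _lgbm_params,
    fit_preliminary,
    internal_validation,
    predict,
    predict_many,
    select_features_and_tune,
    train_rating_model,
)
from frailgait.registry import feature_names


def _noise_matrix(rng, n=150):
    return pd.DataFrame(
        rng.normal(size=(n, 128)), columns=list(feature_names())
    )


def _planted_cohort(rng, n=220, informative=("gait_speed_cm_s",)):
    """Labels driven only by the chosen features; the rest pure noise."""
    X = _noise_matrix(rng, n)
    signal = sum(X[f] for f in informative) / np.sqrt(len(informative))
    fl = 4.5 + 1.2 * signal / signal.std()
    y = pd.Series(np.clip(np.floor(fl).astype(int), 3, 6))
    return X, y


class TestPreliminary:
    def test_single_informative_feature_ranks_first_by_shap(self, rng):
        X, y = _planted_cohort(rng)
        _, importance = fit_preliminary(X, y, TrainingConfig(rng_seed=0))
        assert importance.ranking()[0] == "gait_speed_cm_s"

    def test_shap_additivity_per_sample(self, rng):
        X, y = _planted_cohort(rng, n=120)
        model, importance = fit_preliminary(X, y, TrainingConfig(rng_seed=0))
        pred = model.booster.predict(X)
        recomposed = importance.shap_values.sum(axis=1) + importance.base_value
        assert np.allclose(pred, recomposed, atol=1e-6)

    def test_pure_noise_importance_below_permutation_null(self, rng):
        X = _noise_matrix(rng, n=120)
        y = pd.Series(rng.integers(3, 7, size=120))
        _, imp = fit_preliminary(X, y, TrainingConfig(rng_seed=1))
        observed_max = imp.mean_abs.iloc[0]
        null_max = []
        perm_rng = np.random.default_rng(99)
        for _ in range(19):
            y_perm = pd.Series(perm_rng.permutation(y.values))
            _, imp_p = fit_preliminary(X, y_perm, TrainingConfig(rng_seed=1))
            null_max.append(imp_p.mean_abs.iloc[0])
        assert observed_max <= np.quantile(null_max, 0.95) * 1.05

    def test_degenerate_constant_target_rejected(self, rng):
        X = _noise_matrix(rng, n=40)
        with pytest.raises(ValueError, match="degenerate"):
            fit_preliminary(X, pd.Series([4] * 40))

    def test_missing_feature_values_rejected(self, rng):
        X = _noise_matrix(rng, n=40)
        X.iloc[3, 5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_preliminary(X, pd.Series(rng.integers(3, 7, 40)))


class TestSelection:
    def test_planted_informative_features_are_selected(self, rng):
        informative = ("gait_speed_cm_s", "total_gait_time_s",
                       "stance_phase_pct")
        X, y = _planted_cohort(rng, n=300, informative=informative)
        cfg = TrainingConfig(rng_seed=0, n_search_rounds=20)
        _, imp = fit_preliminary(X, y, cfg)
        model = select_features_and_tune(X, y, imp, cfg)
        assert set(informative) <= set(model.selected_features)

    def test_same_seed_gives_identical_selection_and_score(self, rng):
        X, y = _planted_cohort(rng, n=150)
        cfg = TrainingConfig(rng_seed=7, n_search_rounds=8)
        _, imp = fit_preliminary(X, y, cfg)
        m1 = select_features_and_tune(X, y, imp, cfg)
        m2 = select_features_and_tune(X, y, imp, cfg)
        assert m1.selected_features == m2.selected_features
        assert m1.cv_score == m2.cv_score

    def test_selected_model_not_worse_than_all_feature_baseline(self, rng):
        X, y = _planted_cohort(rng, n=300, informative=("gait_speed_cm_s",
                                                        "cornering_time_s"))
        cfg = TrainingConfig(rng_seed=0, n_search_rounds=20)
        _, imp = fit_preliminary(X, y, cfg)
        model = select_features_and_tune(X, y, imp, cfg)
        baseline = _cv_rmse(X, y.values.astype(float),
                            _lgbm_params(cfg, X.columns), cfg.cv_folds,
                            cfg.rng_seed)
        assert model.cv_score <= baseline * 1.15  # within ~1 SE of baseline

    def test_invalid_round_count_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_search_rounds=0)


class TestPrediction:
    def test_fl_clipping_and_lower_closed_binning(self):
        assert _clip_fl(np.array([7.4]))[0] == pytest.approx(FL_MAX)
        assert _clip_fl(np.array([2.1]))[0] == pytest.approx(FL_MIN)
        import math
        assert math.floor(3.57) == 3
        assert math.floor(4.0) == 4  # lower-closed: 4 <= FL < 5 -> CFS 4

    def test_predictions_respect_fl_contract(self, rng, small_cohort):
        X, y, _ = small_cohort
        cfg = TrainingConfig(rng_seed=0, n_search_rounds=5)
        model, _ = train_rating_model(X, y, cfg)
        preds = predict_many(model, X)
        assert ((preds["fl"] >= FL_MIN) & (preds["fl"] <= FL_MAX)).all()
        assert (preds["predicted_cfs"] == np.floor(preds["fl"])).all()
        assert set(preds["predicted_cfs"]) <= {3, 4, 5, 6}
        one = predict(model, X.iloc[0])
        assert one.fl == pytest.approx(preds["fl"].iloc[0])

    def test_missing_selected_feature_error_names_it(self, rng, small_cohort):
        X, y, _ = small_cohort
        cfg = TrainingConfig(rng_seed=0, n_search_rounds=3)
        model, _ = train_rating_model(X, y, cfg)
        victim = model.selected_features[0]
        with pytest.raises(KeyError, match=victim):
            predict(model, X.iloc[0].drop(victim))

    def test_model_round_trips_through_serialization(self, tmp_path,
                                                     small_cohort):
        from frailgait.model import TrainedModel

        X, y, _ = small_cohort
        cfg = TrainingConfig(rng_seed=0, n_search_rounds=3)
        model, _ = train_rating_model(X, y, cfg)
        model.save(tmp_path / "m.json")
        loaded = TrainedModel.load(tmp_path / "m.json")
        assert loaded.selected_features == model.selected_features
        p1 = predict_many(model, X.head(10))
        p2 = predict_many(loaded, X.head(10))
        assert np.allclose(p1["fl"], p2["fl"])


class TestInternalValidation:
    def test_separable_cohort_reaches_high_fold_kappa(self, rng):
        n = 400
        X = _noise_matrix(rng, n)
        y = pd.Series(rng.integers(3, 7, size=n))
        X["gait_speed_cm_s"] = -y + rng.normal(0, 0.05, n)  # near-separable
        folds = internal_validation(X, y, TrainingConfig(rng_seed=0))
        assert folds["kappa_w"].mean() > 0.9

    def test_shuffled_labels_give_null_kappa(self, rng):
        n = 400
        X = _noise_matrix(rng, n)
        y = pd.Series(rng.permutation(np.repeat([3, 4, 5, 6], n // 4)))
        folds = internal_validation(X, y, TrainingConfig(rng_seed=0))
        assert abs(folds["kappa_w"].mean()) < 0.15

    def test_deterministic_given_seed(self, small_cohort):
        X, y, _ = small_cohort
        cfg = TrainingConfig(rng_seed=4)
        f1 = internal_validation(X, y, cfg)
        f2 = internal_validation(X, y, cfg)
        pd.testing.assert_frame_equal(f1, f2)


def test_monotone_constraint_makes_fl_nondecreasing_in_gait_time(small_cohort):
    X, y, _ = small_cohort
    cfg = TrainingConfig(rng_seed=0, n_search_rounds=4,
                         monotone={"total_gait_time_s": 1})
    model, _ = train_rating_model(X, y, cfg)
    base = X.iloc[7].copy()
    grid = np.linspace(3.0, 25.0, 30)
    fls = []
    for v in grid:
        row = base.copy()
        row["total_gait_time_s"] = v
        fls.append(predict(model, row).fl)
    assert all(b >= a - 1e-9 for a, b in zip(fls, fls[1:]))
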