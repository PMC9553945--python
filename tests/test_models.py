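"""Model families: logistic MLE, boosted trees, tuning, serialization."""

import math

import numpy as np
import pandas as pd
import pytest

import calicohort as cc
from calicohort.metrics import logloss
from calicohort.models import (
    DEFAULT_GBDT_PARAMS,
    BoostedTreesRisk,
    BoostedTreesRiskResults,
    HyperparameterSearchSpace,
    LogisticRisk,
    LogisticRiskResults,
    PerfectSeparationError,
    sigmoid,
    tune_gbdt,
)


class TestSigmoid:
    def test_known_values(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(math.log(3)) == pytest.approx(0.75, abs=1e-12)
        assert sigmoid(-1.0) == pytest.approx(1 - sigmoid(1.0), abs=1e-15)

    def test_saturation_without_overflow(self):
        assert sigmoid(-1e4) == 0.0
        assert sigmoid(1e4) == 1.0


class TestLogisticRisk:
    def test_parameter_count_is_d_plus_one(self, small_cohort):
        res = LogisticRisk.from_clean_cohort(small_cohort).fit()
        assert res.n_parameters == 17  # 16 predictors + intercept
        assert res.converged

    def test_intercept_only_closed_form(self):
        # no predictors: the MLE intercept is the logit of the base rate
        y = np.zeros(1000, dtype=int)
        y[:57] = 1
        X = pd.DataFrame(index=range(1000))
        res = LogisticRisk(X, y).fit()
        assert res.n_parameters == 1
        assert res.intercept == pytest.approx(math.log(0.057 / 0.943), abs=1e-6)

    def test_prediction_matches_hand_score(self, small_cohort):
        res = LogisticRisk.from_clean_cohort(small_cohort).fit()
        row = small_cohort.X.iloc[[3]]
        scaled = res.scaling.apply(row).iloc[0]
        score = res.intercept + sum(
            res.weights[c] * scaled[c] for c in small_cohort.X.columns)
        assert res.predict(row)[0] == pytest.approx(sigmoid(score), abs=1e-12)

    def test_zero_weight_model_predicts_half(self, small_cohort):
        res = LogisticRisk.from_clean_cohort(small_cohort).fit()
        res.params[:] = 0.0
        p = res.predict(small_cohort.X.head(5))
        assert p == pytest.approx(np.full(5, 0.5))

    def test_monotone_likelihood_beats_intercept_only(self, small_cohort):
        res = LogisticRisk.from_clean_cohort(small_cohort).fit()
        p = res.predict(small_cohort.X)
        base = np.full(small_cohort.n, small_cohort.y.mean())
        assert logloss(p, small_cohort.y) <= logloss(base, small_cohort.y)

    def test_single_class_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="both classes"):
            LogisticRisk(small_cohort.X, np.zeros(small_cohort.n, dtype=int))

    def test_perfect_separation_reported(self, small_cohort):
        X = small_cohort.X.head(300).reset_index(drop=True)
        y = (X["HbA1c"] > X["HbA1c"].median()).astype(int).to_numpy()
        with pytest.raises(PerfectSeparationError):
            LogisticRisk(X, y).fit()

    def test_schema_mismatch_lists_columns(self, small_cohort):
        res = LogisticRisk.from_clean_cohort(small_cohort).fit()
        bad = small_cohort.X.drop(columns=["TG"]).assign(bogus=1.0)
        with pytest.raises(ValueError) as err:
            res.predict(bad)
        assert "TG" in str(err.value) and "bogus" in str(err.value)

    def test_json_round_trip(self, small_cohort, tmp_path):
        res = LogisticRisk.from_clean_cohort(small_cohort).fit()
        path = tmp_path / "lr.json"
        res.to_json(path)
        back = LogisticRiskResults.from_json(path)
        np.testing.assert_allclose(back.predict(small_cohort.X.head(50)),
                                   res.predict(small_cohort.X.head(50)),
                                   atol=1e-12)


class TestBoostedTreesRisk:
    def test_deterministic_given_seed(self, small_cohort):
        a = BoostedTreesRisk.from_clean_cohort(small_cohort, seed=4).fit()
        b = BoostedTreesRisk.from_clean_cohort(small_cohort, seed=4).fit()
        np.testing.assert_array_equal(a.predict(small_cohort.X),
                                      b.predict(small_cohort.X))
        assert a.best_iteration == b.best_iteration

    def test_empty_validation_rejected(self, small_cohort):
        model = BoostedTreesRisk.from_clean_cohort(small_cohort,
                                                   validation_fraction=0.0)
        with pytest.raises(ValueError, match="validation"):
            model.fit()

    def test_single_tree_single_split_is_piecewise_constant(self):
        # one boolean feature, one tree of two leaves at learning rate 1:
        # predictions must take exactly two values, sigma(leaf score) each
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=400)
        y = (rng.random(400) < np.where(x == 1, 0.8, 0.2)).astype(int)
        X = pd.DataFrame({"x": x.astype(float)})
        model = BoostedTreesRisk(
            X, y, params={"num_leaves": 2, "learning_rate": 1.0,
                          "min_data_in_leaf": 5, "feature_fraction": 1.0,
                          "bagging_fraction": 1.0, "bagging_freq": 0,
                          "lambda_l1": 0.0, "lambda_l2": 0.0,
                          "min_sum_hessian_in_leaf": 0.0},
            num_boost_round=1, early_stopping_rounds=1000, seed=0)
        res = model.fit(X_val=X, y_val=y)
        p = res.predict(X)
        assert res.best_iteration == 1
        assert len(np.unique(p)) == 2
        raw = res.booster.predict(X.astype(float), raw_score=True)
        np.testing.assert_allclose(p, sigmoid(raw), atol=1e-12)
        # leaf grouping follows the split on x
        assert len(np.unique(p[x == 0])) == 1 and len(np.unique(p[x == 1])) == 1

    def test_monotone_transform_invariance(self, small_cohort):
        params = {**DEFAULT_GBDT_PARAMS, "feature_fraction": 1.0,
                  "bagging_fraction": 1.0, "bagging_freq": 0}
        res_a = BoostedTreesRisk.from_clean_cohort(
            small_cohort, params=params, seed=2).fit()
        X2 = small_cohort.X.copy()
        X2["TG"] = np.log(X2["TG"])  # strictly monotone, applied everywhere
        res_b = BoostedTreesRisk(X2, small_cohort.y, params=params, seed=2).fit()
        np.testing.assert_allclose(
            res_a.predict(small_cohort.X), res_b.predict(X2), atol=1e-9)

    def test_predictions_are_probabilities(self, small_cohort):
        res = BoostedTreesRisk.from_clean_cohort(small_cohort, seed=1).fit()
        p = res.predict(small_cohort.X)
        assert np.all((p >= 0) & (p <= 1))
        assert res.best_iteration <= 1000

    def test_native_round_trip(self, small_cohort, tmp_path):
        res = BoostedTreesRisk.from_clean_cohort(small_cohort, seed=3).fit()
        path = tmp_path / "gbdt.txt"
        res.save(path)
        back = BoostedTreesRiskResults.load(path)
        np.testing.assert_allclose(back.predict(small_cohort.X),
                                   res.predict(small_cohort.X), atol=1e-12)

    def test_summary_reports_trees_and_validation_loss(self, small_cohort):
        res = BoostedTreesRisk.from_clean_cohort(small_cohort, seed=1).fit()
        s = res.summary()
        assert s["n_trees"].iloc[0] == res.best_iteration
        assert s["validation_logloss"].iloc[0] == pytest.approx(
            res.validation_logloss)


class TestEarlyStopping:
    def test_stops_well_before_cap_on_noise(self):
        # pure-noise outcome: validation loss cannot keep improving, so the
        # 30-round rule must end boosting long before the iteration cap
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(2000, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = rng.integers(0, 2, size=2000)
        res = BoostedTreesRisk(X, y, num_boost_round=500, seed=0).fit()
        n_rounds = len(res.evals["validation"]["binary_logloss"])
        assert n_rounds < 500
        assert n_rounds - res.best_iteration <= 30


class TestTuneGbdt:
    def _data(self, small_cohort):
        return small_cohort.X.head(1500).reset_index(drop=True), \
            small_cohort.y[:1500]

    def test_degenerate_space_returns_the_point(self, small_cohort):
        X, y = self._data(small_cohort)
        space = HyperparameterSearchSpace(
            num_leaves=(15, 15), feature_fraction=(0.8, 0.8),
            bagging_fraction=(0.9, 0.9), bagging_freq=(2, 2),
            min_data_in_leaf=(25, 25), lambda_l1=(1e-3, 1e-3),
            lambda_l2=(1e-2, 1e-2), budget=2, seed=0)
        best, score, trials = tune_gbdt(X, y, space=space, k=3)
        assert best["num_leaves"] == 15
        assert best["bagging_freq"] == 2
        assert best["min_data_in_leaf"] == 25
        assert score > 0

    def test_budget_one_returns_single_sample(self, small_cohort):
        X, y = self._data(small_cohort)
        space = HyperparameterSearchSpace(budget=1, seed=7)
        best, _, trials = tune_gbdt(X, y, space=space, k=3)
        assert len(trials) == 1
        assert best == {k: v for k, v in trials.iloc[0].items()
                        if k in best}

    def test_incumbent_monotone(self, small_cohort):
        X, y = self._data(small_cohort)
        space = HyperparameterSearchSpace(budget=4, seed=3)
        _, _, trials = tune_gbdt(X, y, space=space, k=3)
        inc = trials["incumbent_logloss"].to_numpy()
        assert (np.diff(inc) <= 1e-15).all()

    def test_invalid_space_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterSearchSpace(feature_fraction=(0.0, 1.0))
        with pytest.raises(ValueError):
            HyperparameterSearchSpace(budget=0)
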