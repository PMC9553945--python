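"""Risk models: logistic regression and gradient-boosted decision trees.

Both families estimate the conditional outcome probability
p(y=1 | x) = sigma(g(x)): for logistic regression g is linear in the
standardized predictors (d + 1 free parameters, fitted by unpenalized
maximum likelihood); for the boosted ensemble g is an additive sum of
decision trees grown stagewise on the Logloss objective with early
stopping on a held-out validation split (training delegated to LightGBM).

The API follows the model/results idiom: construct a model from data,
call :meth:`fit`, get a results object carrying estimates, diagnostics, a
``summary()`` table and ``predict``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cleaning import CleanCohort, StandardizationParams, standardize
from .cohort import CATEGORICAL_VARS, CONTINUOUS_VARS, PREDICTOR_VARS
from .metrics import logloss

__all__ = [
    "sigmoid",
    "PerfectSeparationError",
    "LogisticRisk",
    "LogisticRiskResults",
    "BoostedTreesRisk",
    "BoostedTreesRiskResults",
    "HyperparameterSearchSpace",
    "tune_gbdt",
    "DEFAULT_GBDT_PARAMS",
]


def sigmoid(x):
    """Logistic function sigma(x) = 1 / (1 + e^-x), overflow-safe."""
    return expit(x)


class PerfectSeparationError(RuntimeError):
    """Maximum likelihood diverges: a hyperplane separates the classes."""


def _check_design(X: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in X.columns]
    extra = [c for c in X.columns if c not in columns]
    if missing or extra:
        raise ValueError(
            f"design-matrix schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}")
    return X[columns]


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

class LogisticRisk:
    """Unpenalized logistic regression on standardized predictors.

    Continuous columns are standardized to zero mean / unit SD on the
    training data; the fitted scaling travels with the results so test
    data is always scaled with the training parameters.
    """

    def __init__(self, X: pd.DataFrame, y, continuous: tuple[str, ...] | None = None):
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = set(np.unique(y))
        if classes != {0, 1}:
            raise ValueError(f"outcomes must contain both classes, got {sorted(classes)}")
        d = X.shape[1]
        if len(X) <= d + 1:
            raise ValueError(f"need more observations ({len(X)}) than parameters ({d + 1})")
        self.columns = list(X.columns)
        self.continuous = tuple(c for c in (continuous or CONTINUOUS_VARS)
                                if c in self.columns)
        self.X = X
        self.y = y

    @classmethod
    def from_clean_cohort(cls, cohort: CleanCohort) -> "LogisticRisk":
        return cls(cohort.X, cohort.y, continuous=cohort.continuous)

    def fit(self, tol: float = 1e-8, maxiter: int = 500) -> "LogisticRiskResults":
        """Unpenalized maximum-likelihood fit.

        L-BFGS with a gradient-norm stopping rule (``tol``); this also
        handles boundary MLEs where a rare indicator perfectly predicts
        one class and the likelihood flattens as its weight drifts off.
        """
        Xs, _, scaling = standardize(self.X, continuous=self.continuous)
        design = sm.add_constant(Xs.astype(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*[Ss]eparation.*")
            warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
            # boundary MLEs (rare indicator perfectly predicting one class)
            # leave the Hessian singular; bse is NaN there, predictions fine
            warnings.filterwarnings("ignore", message=".*[Hh]essian.*")
            warnings.filterwarnings(
                "ignore", category=RuntimeWarning, message=".*overflow.*")
            try:
                sm_res = sm.Logit(self.y, design).fit(
                    method="lbfgs", maxiter=maxiter, pgtol=tol, factr=10.0,
                    disp=0)
            except Exception as err:  # noqa: BLE001 - rewrap with diagnosis
                raise PerfectSeparationError(
                    f"logistic MLE diverged (likely separable classes): {err}") from err
        if not sm_res.mle_retvals.get("converged", False):
            raise PerfectSeparationError(
                "logistic MLE did not converge; gradient stayed above tolerance")
        if not np.isfinite(sm_res.params).all():
            raise PerfectSeparationError(
                "logistic MLE produced non-finite weights; classes are separable")
        fitted = expit(design.to_numpy() @ np.asarray(sm_res.params))
        if -sm_res.llf / len(self.y) < 1e-6 or (
                ((fitted > 0.5) == self.y.astype(bool)).all()
                and np.abs(sm_res.params).max() > 20):
            raise PerfectSeparationError(
                "training data is perfectly classified with diverging weights: "
                "a hyperplane separates the classes")
        return LogisticRiskResults(model=self, _sm=sm_res, scaling=scaling)


class LogisticRiskResults:
    """Fitted logistic model: weights, standard errors, prediction."""

    def __init__(self, model: LogisticRisk | None, _sm, scaling: StandardizationParams,
                 params: pd.Series | None = None, columns: list[str] | None = None):
        self.model = model
        self._sm = _sm
        self.scaling = scaling
        if _sm is not None:
            self.params = _sm.params  # 'const' + one weight per predictor
            self.bse = _sm.bse
            self.converged = bool(_sm.mle_retvals.get("converged", True))
            self.iterations = int(_sm.mle_retvals.get("iterations", -1))
            self.columns = model.columns
        else:  # deserialized
            self.params = params
            self.bse = None
            self.converged = True
            self.iterations = -1
            self.columns = columns

    @property
    def n_parameters(self) -> int:
        """d + 1: one weight per predictor plus the intercept."""
        return len(self.params)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def weights(self) -> pd.Series:
        return self.params.drop("const")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Probabilities for new rows, scaled with the training parameters."""
        X = _check_design(X, self.columns)
        Xs = self.scaling.apply(X).astype(float)
        score = self.intercept + Xs.to_numpy() @ self.weights.loc[self.columns].to_numpy()
        return expit(score)

    def summary(self):
        """Coefficient table (statsmodels summary for a freshly fitted model)."""
        if self._sm is not None:
            return self._sm.summary()
        return self.params.to_frame("coef")

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "family": "logistic",
            "columns": self.columns,
            "params": {k: float(v) for k, v in self.params.items()},
            "scaling": {"means": self.scaling.means, "sds": self.scaling.sds},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LogisticRiskResults":
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:  # raw JSON string, not a path
            pass
        payload = json.loads(text)
        if payload.get("family") != "logistic":
            raise ValueError("not a serialized logistic model")
        params = pd.Series(payload["params"])
        scaling = StandardizationParams(means=payload["scaling"]["means"],
                                        sds=payload["scaling"]["sds"])
        return cls(model=None, _sm=None, scaling=scaling,
                   params=params, columns=payload["columns"])


# ---------------------------------------------------------------------------
# gradient-boosted trees
# ---------------------------------------------------------------------------

#: untuned LightGBM settings used when no search is run
DEFAULT_GBDT_PARAMS: dict = {
    "num_leaves": 31,
    "learning_rate": 0.05,
    "min_data_in_leaf": 20,
    "feature_fraction": 0.9,
    "bagging_fraction": 0.8,
    "bagging_freq": 1,
    "lambda_l1": 0.0,
    "lambda_l2": 0.0,
}

_FIXED_LGB_PARAMS: dict = {
    "objective": "binary",
    "metric": "binary_logloss",
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
}


class BoostedTreesRisk:
    """Gradient-boosted decision-tree ensemble with early stopping.

    Trees are added stagewise on the Logloss objective; boosting halts
    when the validation Logloss has not improved for
    ``early_stopping_rounds`` consecutive iterations (default 30), and
    predictions use the best iteration.  When no validation set is given,
    a stratified fraction is carved from the training data.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        params: dict | None = None,
        early_stopping_rounds: int = 30,
        num_boost_round: int = 1000,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("outcomes must contain both classes")
        self.columns = list(X.columns)
        self.X, self.y = X, y
        self.params = dict(DEFAULT_GBDT_PARAMS if params is None else params)
        self.early_stopping_rounds = early_stopping_rounds
        self.num_boost_round = num_boost_round
        self.validation_fraction = validation_fraction
        self.seed = seed

    @classmethod
    def from_clean_cohort(cls, cohort: CleanCohort, **kwargs) -> "BoostedTreesRisk":
        return cls(cohort.X, cohort.y, **kwargs)

    def fit(self, X_val: pd.DataFrame | None = None, y_val=None) -> "BoostedTreesRiskResults":
        if (X_val is None) != (y_val is None):
            raise ValueError("provide both X_val and y_val, or neither")
        if X_val is None:
            if not 0.0 < self.validation_fraction < 1.0:
                raise ValueError("early stopping requires a non-empty validation set")
            X_tr, X_val, y_tr, y_val = train_test_split(
                self.X, self.y, test_size=self.validation_fraction,
                stratify=self.y, random_state=self.seed)
        else:
            X_tr, y_tr = self.X, self.y
            X_val = _check_design(X_val, self.columns)
            if len(X_val) == 0:
                raise ValueError("early stopping requires a non-empty validation set")

        params = {**_FIXED_LGB_PARAMS, **self.params, "seed": self.seed}
        dtrain = lgb.Dataset(X_tr.astype(float), label=y_tr,
                             feature_name=self.columns)
        dval = lgb.Dataset(X_val.astype(float), label=np.asarray(y_val),
                           reference=dtrain)
        evals: dict = {}
        booster = lgb.train(
            params,
            dtrain,
            num_boost_round=self.num_boost_round,
            valid_sets=[dval],
            valid_names=["validation"],
            callbacks=[
                lgb.early_stopping(self.early_stopping_rounds, verbose=False),
                lgb.record_evaluation(evals),
            ],
        )
        return BoostedTreesRiskResults(model=self, booster=booster,
                                       evals=evals, columns=self.columns)


class BoostedTreesRiskResults:
    """Fitted boosted ensemble: best iteration, validation trace, prediction."""

    def __init__(self, model: BoostedTreesRisk | None, booster: lgb.Booster,
                 evals: dict | None = None, columns: list[str] | None = None):
        self.model = model
        self.booster = booster
        self.evals = evals or {}
        self.columns = columns or booster.feature_name()
        self.best_iteration = int(booster.best_iteration or booster.num_trees())

    @property
    def n_trees(self) -> int:
        return self.best_iteration

    @property
    def validation_logloss(self) -> float:
        trace = self.evals.get("validation", {}).get("binary_logloss")
        if not trace:
            return float("nan")
        return float(trace[self.best_iteration - 1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = _check_design(X, self.columns)
        return np.asarray(self.booster.predict(
            X.astype(float), num_iteration=self.best_iteration))

    def summary(self) -> pd.DataFrame:
        """One-row diagnostic table: trees kept, validation loss, settings."""
        hp = self.model.params if self.model is not None else {}
        return pd.DataFrame([{
            "n_trees": self.best_iteration,
            "validation_logloss": self.validation_logloss,
            **hp,
        }])

    def save(self, path) -> None:
        """Round-trippable native LightGBM text format."""
        self.booster.save_model(str(path), num_iteration=self.best_iteration)

    @classmethod
    def load(cls, path) -> "BoostedTreesRiskResults":
        booster = lgb.Booster(model_file=str(path))
        return cls(model=None, booster=booster)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class HyperparameterSearchSpace:
    """Random-search ranges for the seven tuned LightGBM parameters.

    Counts are sampled log-uniformly, fractions uniformly, regularization
    strengths log-uniformly.  A degenerate (point) range always returns
    its single value.
    """

    num_leaves: tuple[int, int] = (8, 256)
    feature_fraction: tuple[float, float] = (0.4, 1.0)
    bagging_fraction: tuple[float, float] = (0.4, 1.0)
    bagging_freq: tuple[int, int] = (1, 7)
    min_data_in_leaf: tuple[int, int] = (5, 100)
    lambda_l1: tuple[float, float] = (1e-8, 10.0)
    lambda_l2: tuple[float, float] = (1e-8, 10.0)
    budget: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("trial budget must be >= 1")
        for name in ("feature_fraction", "bagging_fraction"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"{name} range must lie in (0, 1]")
        for name in ("num_leaves", "bagging_freq", "min_data_in_leaf"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range must satisfy 1 <= low <= high")

    def sample(self, rng: np.random.Generator) -> dict:
        def log_int(lo, hi):
            return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))

        def log_float(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return {
            "learning_rate": 0.05,
            "num_leaves": log_int(*self.num_leaves),
            "feature_fraction": float(rng.uniform(*self.feature_fraction)),
            "bagging_fraction": float(rng.uniform(*self.bagging_fraction)),
            "bagging_freq": int(rng.integers(self.bagging_freq[0],
                                             self.bagging_freq[1] + 1)),
            "min_data_in_leaf": log_int(*self.min_data_in_leaf),
            "lambda_l1": log_float(*self.lambda_l1),
            "lambda_l2": log_float(*self.lambda_l2),
        }


def tune_gbdt(
    X: pd.DataFrame,
    y,
    space: HyperparameterSearchSpace | None = None,
    k: int = 5,
    early_stopping_rounds: int = 30,
    num_boost_round: int = 1000,
) -> tuple[dict, float, pd.DataFrame]:
    """Seeded random search minimizing out-of-fold Logloss.

    Each trial scores one sampled configuration by stratified k-fold
    cross-validation with early stopping inside every fold (the held-out
    fold doubles as the validation set).  Returns the incumbent
    configuration, its CV Logloss, and the trial log.
    """
    space = space or HyperparameterSearchSpace()
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(space.seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=space.seed)
    folds = list(skf.split(X, y))

    rows, failures = [], []
    best_params, best_score = None, np.inf
    for trial in range(space.budget):
        params = space.sample(rng)
        try:
            scores = []
            for train_idx, val_idx in folds:
                model = BoostedTreesRisk(
                    X.iloc[train_idx], y[train_idx], params=params,
                    early_stopping_rounds=early_stopping_rounds,
                    num_boost_round=num_boost_round, seed=space.seed)
                res = model.fit(X_val=X.iloc[val_idx], y_val=y[val_idx])
                scores.append(logloss(res.predict(X.iloc[val_idx]), y[val_idx]))
            score = float(np.mean(scores))
        except Exception as err:  # noqa: BLE001 - log and continue the search
            failures.append((trial, str(err)))
            continue
        if score < best_score:
            best_params, best_score = params, score
        rows.append({"trial": trial, "cv_logloss": score,
                     "incumbent_logloss": best_score, **params})
    if best_params is None:
        raise RuntimeError(f"all {space.budget} tuning trials failed: {failures}")
    return best_params, best_score, pd.DataFrame(rows)
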