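"""Synthetic health-checkup cohort generator.

The real checkup database behind the published marginals cannot be shared,
so this module builds raw cohorts whose *cleaned* form reproduces its
statistical structure: quartile-matched marginals for the eight continuous
predictors, the printed prevalences for the eight categorical ones, a
~5.7% three-year incident-diabetes outcome, and the data pathologies the
cleaning pipeline must handle (missing cells, sentinel codes such as 0 and
999.9, sex/birthday inconsistencies, absent follow-ups, baseline diabetes
history).

The generative model:

* continuous labs follow log-normals matched to the printed
  median/quartiles (strictly positive, right-skewed); age follows an
  integer-discretized equal-mass two-piece normal bounded to [40, 95],
  matching its asymmetric quartiles;
* an optional Gaussian copula imposes rank correlation between continuous
  predictors (default: independent);
* the true risk is a logistic model on standardized predictors with a
  configurable nonlinear part (hinges, threshold steps, pairwise
  products).  Setting every nonlinear coefficient to zero yields a world
  in which plain logistic regression is exactly correctly specified;
* the intercept is calibrated by root finding so the mean true risk hits
  the target prevalence;
* outcome labels are drawn first and follow-up FPG/HbA1c/drug records are
  back-filled to agree with them, so prevalence stays under the risk
  model's control.

Everything is reproducible from a single root seed via hierarchical
``numpy`` seed sequences, one substream per generation stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri
from scipy.optimize import brentq

from . import table1

__all__ = [
    "CONTINUOUS_VARS",
    "CATEGORICAL_VARS",
    "PREDICTOR_VARS",
    "UP_LEVELS",
    "VariableSpec",
    "NonlinearTerm",
    "RiskModelSpec",
    "PathologyRates",
    "SyntheticConfig",
    "RawCohort",
    "fit_lognormal_from_quartiles",
    "sample_predictors",
    "true_risk",
    "calibrate_intercept",
    "generate_cohort",
    "default_variable_specs",
    "default_risk_spec",
    "default_config",
]

#: canonical predictor order of the cleaned design matrix (d = 16)
CONTINUOUS_VARS = ["BMI", "SBP", "TG", "HDL_C", "LDL_C", "ALT", "HbA1c", "age"]
CATEGORICAL_VARS = ["sex", "smoking", "anti_HTN", "anti_DLP", "UP",
                    "MH_heart", "MH_stroke", "MH_renal"]
PREDICTOR_VARS = CONTINUOUS_VARS + CATEGORICAL_VARS

#: urinary-protein dipstick levels, negative to strongly positive
UP_LEVELS = ["-", "+-", "1+", "2+", "3+"]
UP_POSITIVE_LEVELS = frozenset({"1+", "2+", "3+"})

_Z75 = 0.6744898  # standard normal upper quartile


# ---------------------------------------------------------------------------
# variable specifications and marginal families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Marginal specification for one baseline predictor.

    ``kind`` is one of ``continuous`` (log-normal, or bounded discrete
    two-piece normal when ``discrete``), ``binary`` (Bernoulli) or
    ``ordinal`` (categorical over ``level_probs``).
    """

    name: str
    kind: Literal["continuous", "binary", "ordinal"]
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    prevalence: float | None = None
    level_probs: dict[str, float] | None = None
    missing_rate: float = 0.0
    abnormal_codes: tuple[float, ...] = ()
    abnormal_rate: float = 0.0
    discrete: bool = False
    lower: float | None = None
    upper: float | None = None
    decimals: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate must be in [0, 1]")
        if not 0.0 <= self.abnormal_rate <= 1.0:
            raise ValueError(f"{self.name}: abnormal_rate must be in [0, 1]")
        if self.kind == "continuous":
            if self.median is None or self.q1 is None or self.q3 is None:
                raise ValueError(f"{self.name}: continuous spec needs median/q1/q3")
            if not self.q1 <= self.median <= self.q3:
                raise ValueError(f"{self.name}: need q1 <= median <= q3")
            if self.q1 == self.q3:
                raise ValueError(f"{self.name}: degenerate quartiles (q1 == q3)")
        elif self.kind == "binary":
            if self.prevalence is None or not 0.0 <= self.prevalence <= 1.0:
                raise ValueError(f"{self.name}: binary spec needs prevalence in [0, 1]")
        elif self.kind == "ordinal":
            if not self.level_probs:
                raise ValueError(f"{self.name}: ordinal spec needs level_probs")
            total = sum(self.level_probs.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.level_probs.values()):
                raise ValueError(f"{self.name}: level_probs must be a probability vector")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    # -- marginal machinery -------------------------------------------------

    def lognormal_params(self) -> tuple[float, float]:
        return fit_lognormal_from_quartiles(self.median, self.q1, self.q3)

    def split_lognormal_params(self) -> tuple[float, float, float]:
        """(mu, sigma_low, sigma_high) of the quartile-exact two-piece fit.

        Printed quartiles are not always log-symmetric (HDL-C's are not),
        so each half of the log-scale IQR gets its own sigma; the fit
        reduces to the plain log-normal when ln(med/q1) = ln(q3/med).
        """
        mu, _ = self.lognormal_params()  # validates positivity/ordering
        sig_lo = math.log(self.median / self.q1) / _Z75
        sig_hi = math.log(self.q3 / self.median) / _Z75
        return mu, sig_lo, sig_hi

    def _discrete_support(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer support and pmf of the bounded two-piece normal."""
        lo = int(self.lower if self.lower is not None else self.median - 5 * (self.q3 - self.q1))
        hi = int(self.upper if self.upper is not None else self.median + 5 * (self.q3 - self.q1))
        grid = np.arange(lo, hi + 1, dtype=float)
        sig_lo = (self.median - self.q1) / _Z75
        sig_hi = (self.q3 - self.median) / _Z75
        # equal-mass mixture of two half-normals about the median: the
        # continuous cdf hits 0.25/0.50/0.75 exactly at q1/median/q3
        edges = np.concatenate([[lo - 0.5], grid + 0.5])
        z = edges - self.median
        cdf = np.where(z < 0, ndtr(z / sig_lo), ndtr(z / sig_hi))
        pmf = np.diff(cdf)
        pmf /= pmf.sum()
        return grid, pmf

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the marginal (continuous kinds only)."""
        if self.kind != "continuous":
            raise ValueError(f"{self.name}: ppf defined for continuous variables only")
        u = np.asarray(u, dtype=float)
        if self.discrete:
            grid, pmf = self._discrete_support()
            cdf = np.cumsum(pmf)
            idx = np.searchsorted(cdf, u, side="left")
            return grid[np.minimum(idx, len(grid) - 1)]
        mu, sig_lo, sig_hi = self.split_lognormal_params()
        z = ndtri(u)
        sigma = np.where(z < 0, sig_lo, sig_hi)
        return np.round(np.exp(mu + sigma * z), self.decimals)

    def moments(self) -> tuple[float, float]:
        """Theoretical (mean, sd) of the generative marginal."""
        if self.kind != "continuous":
            raise ValueError(f"{self.name}: moments defined for continuous variables only")
        if self.discrete:
            grid, pmf = self._discrete_support()
            mean = float(grid @ pmf)
            sd = float(np.sqrt(((grid - mean) ** 2) @ pmf))
            return mean, sd
        # two-piece fit has no closed-form moments; Gauss-style quadrature
        # over the latent normal is exact to grid resolution
        mu, sig_lo, sig_hi = self.split_lognormal_params()
        z = np.linspace(-8.0, 8.0, 4001)
        w = np.exp(-0.5 * z**2) / math.sqrt(2.0 * math.pi)
        w /= w.sum()
        x = np.exp(mu + np.where(z < 0, sig_lo, sig_hi) * z)
        mean = float(x @ w)
        sd = float(math.sqrt(((x - mean) ** 2) @ w))
        return mean, sd


def fit_lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal ``(mu, sigma)`` matching a printed median and quartiles.

    Closed-form inversion: ``exp(mu)`` equals the median and
    ``sigma = ln(q3/q1) / (2 z_0.75)`` so that the implied quartiles
    bracket the printed ones symmetrically on the log scale.
    """
    if min(median, q1, q3) <= 0:
        raise ValueError("quartile-matched log-normal requires positive median/q1/q3")
    if not q1 <= median <= q3:
        raise ValueError("need q1 <= median <= q3")
    if q1 == q3:
        raise ValueError("degenerate quartiles: q1 == q3 gives sigma = 0")
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


# ---------------------------------------------------------------------------
# risk model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonlinearTerm:
    """One nonlinear contribution to the true log-odds.

    ``hinge``: coef * max(0, z - threshold) on one standardized predictor;
    ``step``:  coef * 1[z >= threshold];
    ``product``: coef * prod(z_i) over the listed predictors.
    """

    kind: Literal["hinge", "step", "product"]
    variables: tuple[str, ...]
    coefficient: float
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind in ("hinge", "step") and len(self.variables) != 1:
            raise ValueError(f"{self.kind} term takes exactly one variable")
        if self.kind == "product" and len(self.variables) < 2:
            raise ValueError("product term takes at least two variables")
        unknown = set(self.variables) - set(PREDICTOR_VARS)
        if unknown:
            raise ValueError(f"unknown predictors in nonlinear term: {sorted(unknown)}")


@dataclass
class RiskModelSpec:
    """True conditional-risk model p(y=1 | x) of the synthetic world.

    Linear coefficients act on standardized continuous predictors
    (log-odds per generative SD) and on raw 0/1 categorical indicators.
    With all nonlinear coefficients at zero the world is exactly the one
    a plain logistic regression assumes.
    """

    linear_coefficients: dict[str, float]
    nonlinear_terms: tuple[NonlinearTerm, ...] = ()
    intercept: float = 0.0
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.linear_coefficients) - set(PREDICTOR_VARS)
        if unknown:
            raise ValueError(f"unknown predictors in linear coefficients: {sorted(unknown)}")
        if self.target_prevalence is not None and not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")

    def linear_world(self) -> "RiskModelSpec":
        """Copy with every nonlinear coefficient set to zero."""
        return dataclasses.replace(self, nonlinear_terms=())


@dataclass(frozen=True)
class PathologyRates:
    """Rates at which raw-data defects are injected, all in [0, 1]."""

    inconsistent: float = 0.0
    no_followup: float = 0.0
    diabetes_history: float = 0.0
    history_missing: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pathology rate {f.name} must be in [0, 1]")


@dataclass
class SyntheticConfig:
    """Full recipe for one raw synthetic cohort."""

    n_participants: int
    variable_specs: dict[str, VariableSpec]
    risk_spec: RiskModelSpec
    correlation: np.ndarray | None = None  # over CONTINUOUS_VARS order
    pathology_rates: PathologyRates = field(default_factory=PathologyRates)
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(PREDICTOR_VARS) - set(self.variable_specs)
        if missing:
            raise ValueError(f"variable_specs missing predictors: {sorted(missing)}")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            k = len(CONTINUOUS_VARS)
            if r.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k} over {CONTINUOUS_VARS}")
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")
            self.correlation = r

    def standardization_moments(self) -> dict[str, tuple[float, float]]:
        """Theoretical (mean, sd) per continuous predictor."""
        return {v: self.variable_specs[v].moments() for v in CONTINUOUS_VARS}

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_predictors(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a complete (no-missing) predictor table of size ``n_participants``.

    Continuous variables come from their quantile functions applied to
    uniforms — correlated through a Gaussian copula when
    ``config.correlation`` is set, independent otherwise.  Binary
    variables are Bernoulli draws; UP is drawn over its dipstick levels.
    """
    n = config.n_participants
    cols: dict[str, np.ndarray] = {}

    k = len(CONTINUOUS_VARS)
    if config.correlation is not None:
        # Gaussian copula: correlated normals -> uniforms -> marginal ppf
        w, v = np.linalg.eigh(config.correlation)
        root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        z = rng.standard_normal((n, k)) @ root.T
        u = ndtr(z)
    else:
        u = rng.random((n, k))
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    for j, name in enumerate(CONTINUOUS_VARS):
        cols[name] = config.variable_specs[name].ppf(u[:, j])

    for name in CATEGORICAL_VARS:
        spec = config.variable_specs[name]
        if spec.kind == "binary":
            cols[name] = (rng.random(n) < spec.prevalence).astype(np.int64)
        else:  # ordinal (UP dipstick levels)
            levels = list(spec.level_probs)
            probs = np.array([spec.level_probs[lv] for lv in levels])
            cols[name] = rng.choice(levels, size=n, p=probs / probs.sum())

    return pd.DataFrame(cols, columns=PREDICTOR_VARS)


def _risk_design(X: pd.DataFrame, moments: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Standardized continuous + 0/1 categorical view used by the risk model."""
    out = {}
    for name in CONTINUOUS_VARS:
        mean, sd = moments[name]
        out[name] = (np.asarray(X[name], dtype=float) - mean) / sd
    for name in CATEGORICAL_VARS:
        col = X[name]
        if name == "UP" and col.dtype == object:
            out[name] = col.isin(UP_POSITIVE_LEVELS).astype(float).to_numpy()
        else:
            out[name] = np.asarray(col, dtype=float)
    return pd.DataFrame(out, columns=PREDICTOR_VARS)


def _risk_score(Z: pd.DataFrame, spec: RiskModelSpec) -> np.ndarray:
    """Log-odds contribution of everything except the intercept."""
    s = np.zeros(len(Z))
    for name, coef in spec.linear_coefficients.items():
        s += coef * Z[name].to_numpy()
    for term in spec.nonlinear_terms:
        if term.kind == "hinge":
            z = Z[term.variables[0]].to_numpy()
            s += term.coefficient * np.maximum(0.0, z - term.threshold)
        elif term.kind == "step":
            z = Z[term.variables[0]].to_numpy()
            s += term.coefficient * (z >= term.threshold)
        else:  # product
            prod = np.ones(len(Z))
            for v in term.variables:
                prod *= Z[v].to_numpy()
            s += term.coefficient * prod
    return s


def true_risk(
    X: pd.DataFrame,
    spec: RiskModelSpec,
    moments: dict[str, tuple[float, float]],
) -> np.ndarray:
    """True conditional outcome probability for complete predictor rows."""
    for name in PREDICTOR_VARS:
        if X[name].isna().any():
            raise ValueError(f"true_risk requires complete data; {name} has missing values")
    Z = _risk_design(X, moments)
    return expit(spec.intercept + _risk_score(Z, spec))


def calibrate_intercept(
    spec: RiskModelSpec,
    covariate_sample: pd.DataFrame,
    target_prevalence: float,
    moments: dict[str, tuple[float, float]],
    tol: float = 1e-6,
) -> float:
    """Intercept for which the mean true risk over the sample hits the target.

    The mean risk is strictly increasing in the intercept, so bisection
    (Brent) on an automatically widened bracket converges monotonically.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0, 1)")
    Z = _risk_design(covariate_sample, moments)
    s = _risk_score(Z, spec)

    def gap(b: float) -> float:
        return float(np.mean(expit(b + s))) - target_prevalence

    lo, hi = -10.0, 10.0
    for _ in range(60):
        if gap(lo) < 0.0 < gap(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("calibrate_intercept: could not bracket the target prevalence")
    return float(brentq(gap, lo, hi, xtol=tol))


# ---------------------------------------------------------------------------
# raw cohort container
# ---------------------------------------------------------------------------

_BASELINE_COLS = (["record_type", "id"] + PREDICTOR_VARS
                  + ["diabetes_history", "inconsistent"])
_FOLLOWUP_COLS = ["record_type", "id", "followup_offset_days",
                  "followup_FPG", "followup_HbA1c", "followup_drug"]
CSV_COLUMNS = (["record_type", "id"] + PREDICTOR_VARS
               + ["diabetes_history", "inconsistent",
                  "followup_offset_days", "followup_FPG",
                  "followup_HbA1c", "followup_drug"])


@dataclass
class RawCohort:
    """One baseline row per participant plus long-format follow-up records.

    ``baseline`` columns: ``id``, the 16 predictors (continuous floats,
    binary 0/1, UP dipstick levels; missing as NaN, sentinel codes as
    literal values), ``diabetes_history`` (0/1/NaN) and ``inconsistent``
    (0/1 sex-or-birthday inconsistency flag).  ``followups`` columns:
    ``id``, ``followup_offset_days`` (days since baseline),
    ``followup_FPG`` (mg/dL), ``followup_HbA1c`` (%), ``followup_drug``
    (0/1 self-reported anti-diabetic treatment).
    """

    baseline: pd.DataFrame
    followups: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.baseline)

    def to_csv(self, path) -> None:
        """Single-file CSV: baseline rows then follow-up rows, empty = missing."""
        base = self.baseline.copy()
        base.insert(0, "record_type", "baseline")
        fup = self.followups.copy()
        fup.insert(0, "record_type", "followup")
        table = pd.concat([base, fup], axis=0, ignore_index=True)
        table = table.reindex(columns=CSV_COLUMNS)
        table.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "RawCohort":
        from .reporting import read_cohort  # strict parser lives with the IO layer
        return read_cohort(path)

    def __eq__(self, other) -> bool:  # convenience for round-trip tests
        if not isinstance(other, RawCohort):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.baseline.reset_index(drop=True),
                other.baseline.reset_index(drop=True), check_dtype=False)
            pd.testing.assert_frame_equal(
                self.followups.reset_index(drop=True),
                other.followups.reset_index(drop=True), check_dtype=False)
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# follow-up synthesis and pathology injection
# ---------------------------------------------------------------------------

FPG_THRESHOLD = 126.0   # mg/dL, diagnostic fasting plasma glucose
HBA1C_THRESHOLD = 6.5   # %, diagnostic HbA1c
FOLLOWUP_WINDOW_DAYS = 1095  # "within 3 years"


def _synthesize_followups(
    ids: np.ndarray,
    y: np.ndarray,
    baseline_hba1c: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Back-fill follow-up records agreeing with the outcome labels.

    Every participant gets 1–3 annual-style visits inside the 3-year
    window.  Positives receive at least one visit meeting the diagnostic
    rule (high FPG, high HbA1c, or drug self-report, mixed realistically);
    all other visits, and every visit of a negative, stay strictly below
    both thresholds with no drug report.
    """
    n = len(ids)
    n_visits = rng.integers(1, 4, size=n)
    total = int(n_visits.sum())

    rows_id = np.repeat(ids, n_visits)
    rows_base_a1c = np.repeat(baseline_hba1c, n_visits)
    offsets = rng.integers(180, FOLLOWUP_WINDOW_DAYS + 1, size=total)

    # sub-diagnostic defaults for every visit
    fpg = np.clip(np.round(rng.normal(95.0, 11.0, size=total)), 70.0, 125.0)
    hba1c = np.clip(np.round(rows_base_a1c + rng.normal(0.0, 0.15, size=total), 1),
                    4.0, HBA1C_THRESHOLD - 0.1)
    drug = np.zeros(total, dtype=np.int64)

    # one qualifying visit per positive participant
    first_row = np.concatenate([[0], np.cumsum(n_visits)[:-1]])
    pos = np.flatnonzero(y == 1)
    if len(pos):
        pick = first_row[pos] + rng.integers(0, n_visits[pos])
        mode = rng.choice(3, size=len(pos), p=[0.50, 0.35, 0.15])
        a1c_hi = np.round(np.minimum(HBA1C_THRESHOLD + rng.gamma(2.0, 0.35, size=len(pos)), 12.0), 1)
        fpg_hi = np.round(np.minimum(FPG_THRESHOLD + rng.gamma(2.0, 12.0, size=len(pos)), 320.0))
        m0, m1, m2 = mode == 0, mode == 1, mode == 2
        hba1c[pick[m0]] = a1c_hi[m0]
        fpg[pick[m1]] = fpg_hi[m1]
        drug[pick[m2]] = 1

    return pd.DataFrame({
        "id": rows_id,
        "followup_offset_days": offsets.astype(np.int64),
        "followup_FPG": fpg,
        "followup_HbA1c": hba1c,
        "followup_drug": drug,
    })


def generate_cohort(config: SyntheticConfig) -> RawCohort:
    """Generate a raw cohort: predictors, outcome-consistent follow-ups,
    then injected pathologies, missingness and sentinel codes.

    Fully reproducible: all randomness derives from ``config.seed`` through
    named substreams, so identical configs give byte-identical CSVs.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(ss) for name, ss in zip(
        ["predictors", "intercept", "outcome", "followups", "pathology", "missing"],
        root.spawn(6))}

    X = sample_predictors(config, streams["predictors"])
    moments = config.standardization_moments()

    spec = config.risk_spec
    if spec.target_prevalence is not None:
        intercept = calibrate_intercept(spec, X, spec.target_prevalence, moments)
        spec = dataclasses.replace(spec, intercept=intercept)
    p = true_risk(X, spec, moments)
    y = (streams["outcome"].random(len(X)) < p).astype(np.int64)

    ids = np.arange(1, len(X) + 1, dtype=np.int64)
    followups = _synthesize_followups(ids, y, X["HbA1c"].to_numpy(dtype=float),
                                      streams["followups"])

    prng = streams["pathology"]
    rates = config.pathology_rates
    inconsistent = (prng.random(len(X)) < rates.inconsistent).astype(np.int64)
    history = (prng.random(len(X)) < rates.diabetes_history).astype(float)
    history[prng.random(len(X)) < rates.history_missing] = np.nan
    no_fup = prng.random(len(X)) < rates.no_followup
    if no_fup.any():
        # push every visit of the affected participants beyond the window
        affected = set(ids[no_fup])
        mask = followups["id"].isin(affected).to_numpy()
        shifted = followups.loc[mask, "followup_offset_days"] + FOLLOWUP_WINDOW_DAYS
        followups.loc[mask, "followup_offset_days"] = shifted

    baseline = X.copy()
    mrng = streams["missing"]
    for name in PREDICTOR_VARS:
        vspec = config.variable_specs[name]
        col = baseline[name].to_numpy(dtype=object if vspec.kind == "ordinal" else float)
        if vspec.abnormal_rate > 0 and vspec.abnormal_codes:
            hit = mrng.random(len(col)) < vspec.abnormal_rate
            codes = mrng.choice(np.asarray(vspec.abnormal_codes, dtype=float), size=len(col))
            col = np.where(hit, codes, col)
        if vspec.missing_rate > 0:
            col = np.asarray(col, dtype=object)
            col[mrng.random(len(col)) < vspec.missing_rate] = np.nan
        baseline[name] = col
    baseline.insert(0, "id", ids)
    baseline["diabetes_history"] = history
    baseline["inconsistent"] = inconsistent

    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "intercept": float(spec.intercept),
        "n_participants": int(config.n_participants),
    }
    return RawCohort(baseline=baseline, followups=followups, meta=meta)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_variable_specs(
    missing_rate: float = 0.006,
    abnormal_rate: float = 0.002,
) -> dict[str, VariableSpec]:
    """Marginals matched to the published cohort characteristics.

    Continuous labs get the printed median/quartiles with sentinel codes
    0 and 999.9 injected at a small rate; age is a bounded integer
    marginal; categorical prevalences reproduce the printed counts.  UP's
    dipstick levels split the printed positive mass (5.3%) over 1+/2+/3+
    and the negative mass over -/+- in typical dipstick proportions.
    """
    specs: dict[str, VariableSpec] = {}
    for name, (med, q1, q3) in table1.CONTINUOUS_QUARTILES.items():
        if name == "age":
            specs[name] = VariableSpec(
                name=name, kind="continuous", median=med, q1=q1, q3=q3,
                discrete=True, lower=40, upper=95, decimals=0,
                missing_rate=missing_rate)
        else:
            specs[name] = VariableSpec(
                name=name, kind="continuous", median=med, q1=q1, q3=q3,
                missing_rate=missing_rate,
                abnormal_codes=(0.0, 999.9), abnormal_rate=abnormal_rate)
    up_pos = table1.CATEGORICAL_PREVALENCE["UP"]
    up_neg = 1.0 - up_pos
    for name, prev in table1.CATEGORICAL_PREVALENCE.items():
        if name == "UP":
            specs[name] = VariableSpec(
                name=name, kind="ordinal",
                level_probs={"-": up_neg * 0.915, "+-": up_neg * 0.085,
                             "1+": up_pos * 0.72, "2+": up_pos * 0.21,
                             "3+": up_pos * 0.07},
                missing_rate=missing_rate)
        else:
            specs[name] = VariableSpec(name=name, kind="binary", prevalence=prev,
                                       missing_rate=missing_rate)
    return specs


def default_risk_spec(nonlinear: bool = True) -> RiskModelSpec:
    """Default true-risk model.

    Linear log-odds are set loosely from the published positive/negative
    group contrasts (HbA1c dominant, then treatment flags, adiposity and
    age).  The nonlinear part — a strong hinge above roughly one SD of
    HbA1c (~5.9%, the pre-diabetic range), a milder BMI hinge, and an
    age x BMI product — misspecifies a purely linear logit while staying
    clinically interpretable.  ``nonlinear=False`` removes it, giving an
    exactly LR-correct world.
    """
    linear = {
        "BMI": 0.25, "SBP": 0.15, "TG": 0.20, "HDL_C": -0.25, "LDL_C": -0.08,
        "ALT": 0.15, "HbA1c": 0.90, "age": 0.25,
        "sex": -0.45, "smoking": 0.15, "anti_HTN": 0.45, "anti_DLP": 0.30,
        "UP": 0.40, "MH_heart": 0.30, "MH_stroke": 0.30, "MH_renal": 0.20,
    }
    terms: tuple[NonlinearTerm, ...] = ()
    if nonlinear:
        terms = (
            NonlinearTerm("hinge", ("HbA1c",), 1.30, threshold=1.0),
            NonlinearTerm("hinge", ("BMI",), 0.40, threshold=1.0),
            NonlinearTerm("product", ("age", "BMI"), 0.15),
        )
    return RiskModelSpec(
        linear_coefficients=linear,
        nonlinear_terms=terms,
        target_prevalence=table1.OUTCOME_PREVALENCE,
    )


def default_pathology_rates() -> PathologyRates:
    """Defaults sized so the cleaning funnel loses a fraction comparable to
    the published flowchart (805,816 -> 277,651, ~34% retained)."""
    return PathologyRates(
        inconsistent=1e-5,
        no_followup=0.487,
        diabetes_history=0.18,
        history_missing=0.048,
    )


def default_config(
    n_participants: int,
    seed: int = 0,
    nonlinear: bool = True,
    pathologies: bool = True,
    missing_rate: float | None = None,
    correlation: np.ndarray | None = None,
) -> SyntheticConfig:
    """The study conditions: published marginals, ~5.7% outcome, default
    pathology funnel.  ``pathologies=False`` gives a directly clean world
    (no missing cells, sentinels, or excluded subgroups)."""
    if missing_rate is None:
        missing_rate = 0.006 if pathologies else 0.0
    abnormal_rate = 0.002 if pathologies else 0.0
    return SyntheticConfig(
        n_participants=n_participants,
        variable_specs=default_variable_specs(missing_rate, abnormal_rate),
        risk_spec=default_risk_spec(nonlinear),
        correlation=correlation,
        pathology_rates=default_pathology_rates() if pathologies else PathologyRates(),
        seed=seed,
    )
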