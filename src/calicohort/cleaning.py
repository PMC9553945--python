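"""Participant selection, variable screening and value cleaning.

Mirrors the selection funnel of the source cohort: drop records with
sex/birthday inconsistencies, require a follow-up checkup within three
years (<= 1095 days), exclude baseline diabetes history (or missing
history information), screen variables by missing rate (> 10% dropped)
plus a forced multicollinearity drop list, dichotomize the urinary-protein
dipstick, label the three-year incident-diabetes outcome
(FPG >= 126 mg/dL, HbA1c >= 6.5%, or anti-diabetic drug self-report at any
follow-up), and finally exclude participants with missing values, sentinel
codes (e.g. 0, 999.9) or values beyond the outer 0.05% of either tail of
each continuous distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CATEGORICAL_VARS,
    CONTINUOUS_VARS,
    FOLLOWUP_WINDOW_DAYS,
    FPG_THRESHOLD,
    HBA1C_THRESHOLD,
    PREDICTOR_VARS,
    UP_POSITIVE_LEVELS,
    RawCohort,
)

__all__ = [
    "CleaningParams",
    "CleaningReport",
    "CleanCohort",
    "StandardizationParams",
    "select_participants",
    "screen_variables",
    "dichotomize_up",
    "label_outcome",
    "exclude_abnormal_and_outliers",
    "standardize",
    "clean_cohort",
    "DEFAULT_SENTINELS",
    "DEFAULT_FORCED_DROPS",
]

#: sentinel codes treated as abnormal for every continuous lab value
DEFAULT_SENTINELS: dict[str, tuple[float, ...]] = {
    name: (0.0, 999.9) for name in CONTINUOUS_VARS if name != "age"
}

#: variables removed for multicollinearity in the source analysis
DEFAULT_FORCED_DROPS = ("DBP", "AST", "GGTP", "UG")

_UP_NEGATIVE = {"-", "+-", "±"}
_UP_POSITIVE = set(UP_POSITIVE_LEVELS)


@dataclass
class CleaningParams:
    max_followup_days: int = FOLLOWUP_WINDOW_DAYS
    missing_threshold: float = 0.10
    forced_drops: tuple[str, ...] = DEFAULT_FORCED_DROPS
    tail: float = 0.0005
    sentinels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SENTINELS))


@dataclass
class CleaningReport:
    """Audit trail of the selection funnel and variable screen."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    dropped_variables: list[tuple[str, str]] = field(default_factory=list)

    def record(self, stage: str, count: int) -> None:
        if self.stage_counts:
            last = next(reversed(self.stage_counts.values()))
            if count > last:  # funnel counts can only shrink
                raise ValueError(
                    f"funnel stage {stage}: count {count} exceeds previous {last}")
        self.stage_counts[stage] = int(count)

    def to_dict(self) -> dict:
        return {
            "stage_counts": dict(self.stage_counts),
            "missing_rates": {k: float(v) for k, v in self.missing_rates.items()},
            "dropped_variables": [list(t) for t in self.dropped_variables],
        }


@dataclass
class StandardizationParams:
    """Per-continuous-column mean/SD estimated on training data."""

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, v in self.sds.items() if not v > 0]
        if bad:
            raise ValueError(f"zero or negative standard deviation for: {bad}")

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, mean in self.means.items():
            out[col] = (X[col] - mean) / self.sds[col]
        return out


@dataclass
class CleanCohort:
    """Modeling substrate: N x 16 predictor matrix plus binary outcome."""

    X: pd.DataFrame
    y: np.ndarray
    continuous: tuple[str, ...] = tuple(CONTINUOUS_VARS)
    categorical: tuple[str, ...] = tuple(CATEGORICAL_VARS)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if list(self.X.columns) != PREDICTOR_VARS:
            raise ValueError(f"CleanCohort columns must be exactly {PREDICTOR_VARS}")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.isna().any().any():
            raise ValueError("CleanCohort must not contain missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        up = self.X["UP"]
        if not set(np.unique(up)) <= {0, 1}:
            raise ValueError("UP must be dichotomized to 0/1")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())


# ---------------------------------------------------------------------------
# funnel stages
# ---------------------------------------------------------------------------

def select_participants(
    raw: RawCohort,
    max_followup_days: int = FOLLOWUP_WINDOW_DAYS,
    report: CleaningReport | None = None,
) -> tuple[RawCohort, CleaningReport]:
    """Apply the three participant-selection filters, in funnel order.

    1. drop sex/birthday-inconsistent records;
    2. drop participants without any follow-up within the window;
    3. drop participants with baseline diabetes history or with that
       information missing.
    """
    report = report or CleaningReport()
    base = raw.baseline
    report.record("initial", len(base))

    base = base[base["inconsistent"] != 1]
    report.record("after_consistency", len(base))

    in_window = raw.followups[
        raw.followups["followup_offset_days"] <= max_followup_days]
    has_fup = base["id"].isin(set(in_window["id"]))
    base = base[has_fup]
    report.record("after_followup", len(base))

    hist = base["diabetes_history"]
    base = base[hist.notna() & (hist != 1)]
    report.record("after_history", len(base))

    fups = raw.followups[raw.followups["id"].isin(set(base["id"]))]
    return RawCohort(baseline=base.reset_index(drop=True),
                     followups=fups.reset_index(drop=True),
                     meta=dict(raw.meta)), report


def screen_variables(
    table: pd.DataFrame,
    threshold: float = 0.10,
    forced_drops: tuple[str, ...] = DEFAULT_FORCED_DROPS,
    report: CleaningReport | None = None,
) -> tuple[list[str], CleaningReport]:
    """Retain predictor columns with acceptable missingness.

    Columns whose missing rate exceeds ``threshold`` are dropped, then the
    forced drop list (the multicollinearity screen's stated outcome) is
    removed regardless of missingness.
    """
    report = report or CleaningReport()
    candidates = [c for c in table.columns
                  if c not in ("id", "diabetes_history", "inconsistent", "record_type")]
    retained: list[str] = []
    for col in candidates:
        rate = float(table[col].isna().mean())
        report.missing_rates[col] = rate
        if col in forced_drops:
            report.dropped_variables.append((col, "multicollinearity"))
        elif rate > threshold:
            report.dropped_variables.append((col, f"missing rate {rate:.3f} > {threshold}"))
        else:
            retained.append(col)
    if not retained:
        raise ValueError("variable screen dropped every variable")
    return retained, report


def dichotomize_up(value) -> int:
    """Map a urinary-protein dipstick level to binary: -, +- -> 0; 1+..3+ -> 1."""
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    if value in _UP_NEGATIVE:
        return 0
    if value in _UP_POSITIVE:
        return 1
    raise ValueError(f"unknown urinary-protein level: {value!r}")


def label_outcome(
    followups: pd.DataFrame,
    ids: pd.Series | np.ndarray,
    max_followup_days: int = FOLLOWUP_WINDOW_DAYS,
) -> np.ndarray:
    """Three-year incident-diabetes label per participant.

    Positive iff any follow-up inside the window has FPG >= 126 mg/dL,
    HbA1c >= 6.5%, or a self-reported anti-diabetic drug.  Raises if a
    participant has no in-window follow-up (selection contract violated).
    """
    ids = np.asarray(ids)
    f = followups[followups["followup_offset_days"] <= max_followup_days]
    if not np.isin(ids, f["id"].unique()).all():
        missing = set(ids) - set(f["id"])
        raise ValueError(
            f"{len(missing)} participants have no follow-up within "
            f"{max_followup_days} days; run select_participants first")
    hit = (
        (f["followup_FPG"] >= FPG_THRESHOLD)
        | (f["followup_HbA1c"] >= HBA1C_THRESHOLD)
        | (f["followup_drug"] == 1)
    )
    positive_ids = set(f.loc[hit, "id"])
    return np.isin(ids, list(positive_ids)).astype(np.int64)


def exclude_abnormal_and_outliers(
    X: pd.DataFrame,
    y: np.ndarray,
    tail: float = 0.0005,
    sentinels: dict[str, tuple[float, ...]] | None = None,
    report: CleaningReport | None = None,
) -> tuple[CleanCohort, CleaningReport]:
    """Final exclusion stage on an already-selected predictor table.

    Participants with any missing value or sentinel code are dropped
    first; the two-sided ``tail`` empirical quantiles of each continuous
    variable are then computed over the remaining data, and participants
    with any value strictly outside them are dropped.  ``X`` must carry
    the 16 predictors with UP already dichotomized.
    """
    if tail >= 0.5:
        raise ValueError("tail must be < 0.5")
    report = report or CleaningReport()
    sentinels = dict(DEFAULT_SENTINELS) if sentinels is None else sentinels
    y = np.asarray(y)
    report.record("before_value_cleaning", len(X))

    keep = ~X[PREDICTOR_VARS].isna().any(axis=1)
    for col, codes in sentinels.items():
        if col in X.columns and len(codes):
            keep &= ~X[col].isin(codes)
    X1, y1 = X[keep], y[keep.to_numpy()]
    report.record("after_missing_and_sentinel", len(X1))

    keep2 = np.ones(len(X1), dtype=bool)
    if tail > 0:
        for col in CONTINUOUS_VARS:
            vals = X1[col].to_numpy(dtype=float)
            lo, hi = np.quantile(vals, [tail, 1.0 - tail])
            keep2 &= (vals >= lo) & (vals <= hi)  # ties at the quantile kept
    X2, y2 = X1[keep2], y1[keep2]
    report.record("after_outlier_trim", len(X2))

    X2 = X2[PREDICTOR_VARS].reset_index(drop=True).astype(
        {c: float for c in CONTINUOUS_VARS} | {c: np.int64 for c in CATEGORICAL_VARS})
    return CleanCohort(X=X2, y=y2), report


def standardize(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    continuous: tuple[str, ...] = tuple(CONTINUOUS_VARS),
) -> tuple[pd.DataFrame, pd.DataFrame | None, StandardizationParams]:
    """Zero-mean unit-SD scaling of continuous columns, fitted on train.

    The test table is scaled with the *training* parameters, never its
    own; categorical columns pass through untouched.
    """
    means, sds = {}, {}
    for col in continuous:
        v = train[col].to_numpy(dtype=float)
        sd = float(v.std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"zero-variance continuous column: {col}")
        means[col], sds[col] = float(v.mean()), sd
    params = StandardizationParams(means=means, sds=sds)
    train_s = params.apply(train)
    test_s = params.apply(test) if test is not None else None
    return train_s, test_s, params


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def clean_cohort(
    raw: RawCohort,
    params: CleaningParams | None = None,
) -> tuple[CleanCohort, CleaningReport]:
    """Run the whole funnel: selection, screening, UP dichotomization,
    outcome labeling, and missing/sentinel/outlier exclusion."""
    params = params or CleaningParams()
    selected, report = select_participants(raw, params.max_followup_days)

    retained, report = screen_variables(
        selected.baseline, params.missing_threshold, params.forced_drops, report)
    lost = set(PREDICTOR_VARS) - set(retained)
    if lost:
        raise ValueError(f"variable screen removed required predictors: {sorted(lost)}")

    X = selected.baseline[PREDICTOR_VARS].copy()
    up = X["UP"]
    X["UP"] = np.array([np.nan if pd.isna(v) else dichotomize_up(v) for v in up],
                       dtype=float)
    y = label_outcome(selected.followups, selected.baseline["id"],
                      params.max_followup_days)

    clean, report = exclude_abnormal_and_outliers(
        X, y, tail=params.tail, sentinels=params.sentinels, report=report)
    return clean, report
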