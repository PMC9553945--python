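"""Published marginal summaries of a Japanese health-checkup cohort.

These numbers are the generator's fidelity targets: a cohort of 277,651
insured adults from a prefectural national-health-insurance database,
with baseline checkup measurements and a 3-year incident diabetes
follow-up.  Continuous variables are summarised as
median [Q1, Q3]; categorical ones as counts.  The synthetic generator in
:mod:`calicohort.cohort` matches these marginals; nothing here is estimated
at run time.
"""

from __future__ import annotations

COHORT_N = 277_651
POSITIVE_N = 15_900  # incident diabetes within 3 years

#: prevalence of the outcome in the cleaned cohort (~5.7%)
OUTCOME_PREVALENCE = POSITIVE_N / COHORT_N

#: median, Q1, Q3 for the eight retained continuous predictors
CONTINUOUS_QUARTILES: dict[str, tuple[float, float, float]] = {
    "BMI": (22.3, 20.4, 24.4),      # kg/m^2
    "SBP": (128.0, 118.0, 139.0),   # mmHg
    "TG": (93.0, 69.0, 128.0),      # mg/dL
    "HDL_C": (63.0, 52.0, 73.0),    # mg/dL
    "LDL_C": (124.0, 105.0, 145.0),  # mg/dL
    "ALT": (17.0, 13.0, 22.0),      # IU/L
    "HbA1c": (5.5, 5.3, 5.8),       # %
    "age": (68.0, 63.0, 75.0),      # years
}

#: counts (out of COHORT_N) for the binary predictors; sex counts females
CATEGORICAL_COUNTS: dict[str, int] = {
    "sex": 169_779,       # female
    "smoking": 29_998,
    "anti_HTN": 99_612,
    "anti_DLP": 67_923,
    "UP": 14_696,         # urinary protein positive (1+/2+/3+)
    "MH_heart": 16_462,
    "MH_stroke": 9_605,
    "MH_renal": 1_043,
}

CATEGORICAL_PREVALENCE: dict[str, float] = {
    k: v / COHORT_N for k, v in CATEGORICAL_COUNTS.items()
}

#: participant-selection funnel counts (raw extraction -> analysis set)
FUNNEL_COUNTS: dict[str, int] = {
    "initial": 805_816,
    "after_consistency": 805_809,          # 7 sex/birthday inconsistencies
    "after_followup": 413_611,             # no re-checkup within 3 years
    "after_history": 319_402,              # diabetes history or missing
    "final": 277_651,                      # missing/abnormal/outlier removal
}
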