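"""Selection funnel, variable screen, outcome rule, value cleaning."""

import numpy as np
import pandas as pd
import pytest

import calicohort as cc
from calicohort import table1
from calicohort.cleaning import (
    dichotomize_up,
    exclude_abnormal_and_outliers,
    label_outcome,
    screen_variables,
    select_participants,
    standardize,
)
from calicohort.cohort import PREDICTOR_VARS, default_config, generate_cohort


def _toy_raw(followup_offsets, history=0.0, inconsistent=0):
    """Single-participant raw cohort with given follow-up offsets."""
    base = generate_cohort(default_config(1, seed=0, pathologies=False)).baseline
    base["diabetes_history"] = history
    base["inconsistent"] = inconsistent
    fups = pd.DataFrame({
        "id": [1] * len(followup_offsets),
        "followup_offset_days": followup_offsets,
        "followup_FPG": [100.0] * len(followup_offsets),
        "followup_HbA1c": [5.5] * len(followup_offsets),
        "followup_drug": [0] * len(followup_offsets),
    })
    return cc.RawCohort(baseline=base, followups=fups)


class TestSelectParticipants:
    def test_no_pathologies_no_exclusions(self):
        raw = generate_cohort(default_config(800, seed=3, pathologies=False))
        selected, report = select_participants(raw)
        assert selected.n_participants == 800
        assert report.stage_counts["after_history"] == 800

    def test_followup_beyond_window_excluded(self):
        raw = _toy_raw([1100])
        selected, report = select_participants(raw)
        assert selected.n_participants == 0
        assert report.stage_counts["after_consistency"] == 1
        assert report.stage_counts["after_followup"] == 0

    def test_followup_at_1095_kept(self):
        selected, _ = select_participants(_toy_raw([1095]))
        assert selected.n_participants == 1

    def test_missing_history_excluded(self):
        selected, _ = select_participants(_toy_raw([400], history=np.nan))
        assert selected.n_participants == 0

    def test_inconsistent_excluded_first(self):
        _, report = select_participants(_toy_raw([400], inconsistent=1))
        assert report.stage_counts["after_consistency"] == 0

    def test_default_funnel_matches_published_fractions(self):
        # default pathology rates are sized to the published flowchart:
        # ~34% of raw records survive the whole funnel
        raw = generate_cohort(default_config(20_000, seed=17))
        clean, report = cc.clean_cohort(raw)
        published = table1.FUNNEL_COUNTS["final"] / table1.FUNNEL_COUNTS["initial"]
        assert abs(clean.n / 20_000 - published) < 0.03
        counts = list(report.stage_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))  # monotone funnel


class TestScreenVariables:
    def test_missing_threshold_boundary(self):
        t = pd.DataFrame({
            "a": [np.nan] * 11 + [1.0] * 89,   # 11% missing -> dropped
            "b": [np.nan] * 9 + [1.0] * 91,    # 9% missing -> kept
        })
        retained, report = screen_variables(t, threshold=0.10, forced_drops=())
        assert retained == ["b"]
        assert ("a", "missing rate 0.110 > 0.1") in report.dropped_variables

    def test_forced_drops_removed_regardless_of_missingness(self):
        t = pd.DataFrame({c: [1.0, 2.0] for c in
                          ["DBP", "AST", "GGTP", "UG", "BMI"]})
        retained, report = screen_variables(t)
        assert retained == ["BMI"]
        dropped = {name for name, reason in report.dropped_variables
                   if reason == "multicollinearity"}
        assert dropped == {"DBP", "AST", "GGTP", "UG"}

    def test_identity_with_permissive_settings(self):
        t = pd.DataFrame({"a": [1.0], "b": [np.nan]})
        retained, _ = screen_variables(t, threshold=1.0, forced_drops=())
        assert retained == ["a", "b"]

    def test_all_dropped_is_error(self):
        t = pd.DataFrame({"a": [np.nan] * 10})
        with pytest.raises(ValueError):
            screen_variables(t, threshold=0.05, forced_drops=())


class TestDichotomizeUp:
    @pytest.mark.parametrize("level,expected", [
        ("-", 0), ("+-", 0), ("±", 0), ("1+", 1), ("2+", 1), ("3+", 1),
    ])
    def test_mapping(self, level, expected):
        assert dichotomize_up(level) == expected

    def test_unknown_level_named_in_error(self):
        with pytest.raises(ValueError, match="4\\+"):
            dichotomize_up("4+")

    def test_population_positive_fraction(self):
        # default dipstick level probabilities put 5.3% mass on 1+/2+/3+
        cfg = default_config(200_000, seed=0, pathologies=False)
        X = cc.sample_predictors(cfg, np.random.default_rng(8))
        up = np.array([dichotomize_up(v) for v in X["UP"]])
        assert abs(up.mean() - 0.053) < 0.003


class TestLabelOutcome:
    def _fups(self, rows):
        return pd.DataFrame(rows, columns=["id", "followup_offset_days",
                                           "followup_FPG", "followup_HbA1c",
                                           "followup_drug"])

    def test_hba1c_boundary_is_positive(self):
        f = self._fups([(1, 400, 100.0, 6.5, 0)])
        assert label_outcome(f, [1]) == np.array([1])

    def test_all_subdiagnostic_is_negative(self):
        f = self._fups([(1, 300, 125.0, 6.4, 0)] * 3)
        assert label_outcome(f, [1]) == np.array([0])

    def test_fpg_boundary_at_any_visit(self):
        f = self._fups([(1, 300, 100.0, 5.5, 0), (1, 700, 126.0, 5.5, 0)])
        assert label_outcome(f, [1]) == np.array([1])

    def test_drug_report_is_positive(self):
        f = self._fups([(1, 300, 100.0, 5.5, 1)])
        assert label_outcome(f, [1]) == np.array([1])

    def test_qualifying_visit_outside_window_ignored(self):
        f = self._fups([(1, 300, 100.0, 5.5, 0), (1, 1200, 200.0, 9.0, 1)])
        assert label_outcome(f, [1]) == np.array([0])

    def test_no_followup_is_error(self):
        f = self._fups([(1, 300, 100.0, 5.5, 0)])
        with pytest.raises(ValueError, match="no follow-up"):
            label_outcome(f, [1, 2])


class TestExcludeAbnormalAndOutliers:
    def _clean_X(self, n, seed=0):
        cfg = default_config(n, seed=seed, pathologies=False)
        X = cc.sample_predictors(cfg, np.random.default_rng(seed))
        X["UP"] = X["UP"].isin({"1+", "2+", "3+"}).astype(int)
        return X

    def test_tail_zero_clean_input_is_identity(self):
        X = self._clean_X(500)
        y = np.zeros(500, dtype=int)
        y[:30] = 1
        clean, _ = exclude_abnormal_and_outliers(X, y, tail=0.0)
        assert clean.n == 500
        pd.testing.assert_frame_equal(clean.X, X[PREDICTOR_VARS].astype(clean.X.dtypes))

    def test_sentinel_dropped_at_sentinel_stage(self):
        X = self._clean_X(200)
        X.loc[5, "TG"] = 999.9
        y = (np.arange(200) % 17 == 0).astype(int)
        clean, report = exclude_abnormal_and_outliers(X, y, tail=0.0)
        assert report.stage_counts["after_missing_and_sentinel"] == 199
        assert report.stage_counts["after_outlier_trim"] == 199

    def test_quantile_trim_count_bound(self):
        # 10,000 clean values, tail 5e-4: roughly 5 values fall strictly
        # outside each tail quantile, so per-variable loss stays near 10
        X = self._clean_X(10_000, seed=4)
        one_var = X.copy()
        # freeze all but TG at their medians so only TG can trigger trimming
        for c in cc.CONTINUOUS_VARS:
            if c != "TG":
                one_var[c] = one_var[c].median()
        y = np.zeros(len(X), dtype=int)
        y[:600] = 1
        clean, _ = exclude_abnormal_and_outliers(one_var, y, tail=0.0005)
        dropped = len(X) - clean.n
        assert 2 <= dropped <= 14

    def test_tail_too_large_rejected(self):
        X = self._clean_X(50)
        with pytest.raises(ValueError):
            exclude_abnormal_and_outliers(X, np.zeros(50, int), tail=0.5)


class TestStandardize:
    def test_train_stats_reused_for_test(self):
        train = pd.DataFrame({"x": [0.0, 2.0]})
        test = pd.DataFrame({"x": [1.0]})
        train_s, test_s, params = standardize(train, test, continuous=("x",))
        assert params.means["x"] == 1.0 and params.sds["x"] == 1.0
        assert test_s["x"].iloc[0] == 0.0
        assert train_s["x"].tolist() == [-1.0, 1.0]

    def test_train_equals_test(self, small_cohort):
        X = small_cohort.X
        train_s, test_s, _ = standardize(X, X)
        for c in cc.CONTINUOUS_VARS:
            assert abs(test_s[c].mean()) < 1e-10
            assert abs(test_s[c].std(ddof=0) - 1.0) < 1e-10

    def test_own_stats_differ_from_train_stats(self, small_cohort):
        X = small_cohort.X
        train, test = X.iloc[:2000], X.iloc[2000:]
        _, test_with_train, _ = standardize(train, test)
        test_with_own, _, _ = standardize(test)
        assert not np.allclose(test_with_train["BMI"], test_with_own["BMI"])

    def test_zero_variance_column_named(self):
        train = pd.DataFrame({"x": [1.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="x"):
            standardize(train, continuous=("x", "y"))

    def test_categorical_untouched(self, small_cohort):
        X = small_cohort.X
        train_s, _, _ = standardize(X)
        for c in cc.CATEGORICAL_VARS:
            assert (train_s[c] == X[c]).all()


def test_clean_cohort_idempotent_on_clean_world():
    raw = generate_cohort(default_config(1200, seed=9, pathologies=False))
    params = cc.CleaningParams(tail=0.0)
    first, _ = cc.clean_cohort(raw, params)
    again, _ = exclude_abnormal_and_outliers(first.X, first.y, tail=0.0)
    pd.testing.assert_frame_equal(first.X, again.X)
    assert (first.y == again.y).all()


def test_clean_cohort_invariants_enforced():
    X = pd.DataFrame({c: [0.0, 1.0] for c in PREDICTOR_VARS})
    with pytest.raises(ValueError, match="binary"):
        cc.CleanCohort(X=X, y=np.array([0, 2]))
    X_bad = X.copy()
    X_bad.loc[0, "BMI"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        cc.CleanCohort(X=X_bad, y=np.array([0, 1]))
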