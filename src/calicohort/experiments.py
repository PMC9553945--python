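"""Evaluation protocols: stratified 5-fold CV and the sample-size sweep.

Two protocols drive the whole comparison:

* **Cross-validation** — stratified k-fold (k = 5): each fold in turn is
  the test set, the remainder the training set; ECE, Logloss, AUC and the
  reliability diagram are computed per fold and aggregated as mean ± SD.

* **Sample-size sweep** — one stratified 80/20 split is fixed for the
  whole experiment; for every training size, subsamples are drawn without
  replacement from the 80% pool (default 100 repeats), each model is
  trained on the subsample and evaluated on the *common* 20% test set.
  This traces how calibration and discrimination improve with data, and
  where the flexible model overtakes the linear one.

Everything is a pure function of (cohort, configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cleaning import CleanCohort
from .metrics import MetricSet, ReliabilityDiagram, compute_metrics
from .models import (
    BoostedTreesRisk,
    HyperparameterSearchSpace,
    LogisticRisk,
    tune_gbdt,
)

__all__ = [
    "SplitSpec",
    "CVResult",
    "SweepResult",
    "stratified_kfold",
    "crossvalidate",
    "sample_size_sweep",
    "aggregate",
]

_METRIC_NAMES = ("ece", "logloss", "auc")


@dataclass(frozen=True)
class SplitSpec:
    """How data is partitioned for a protocol run."""

    kind: str = "kfold"          # "kfold" | "holdout"
    k: int = 5
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "holdout"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.kind == "holdout" and not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def aggregate(values) -> tuple[float, float]:
    """Mean and population-SD (denominator n) of a metric list."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty metric list")
    return float(values.mean()), float(values.std(ddof=0))


def stratified_kfold(y, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) preserving the class proportion per fold.

    Fold sizes and per-fold positive counts each differ by at most one.
    """
    y = np.asarray(y)
    counts = np.bincount(y.astype(np.int64), minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"stratification impossible: smallest class has {counts.min()} "
            f"members but k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def _fit_predict(
    model_name: str,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    seed: int,
    gbdt_params: dict | None,
) -> np.ndarray:
    if model_name == "lr":
        res = LogisticRisk(X_train, y_train).fit()
    elif model_name == "gbdt":
        res = BoostedTreesRisk(X_train, y_train, params=gbdt_params,
                               seed=seed).fit()
    else:
        raise ValueError(f"unknown model {model_name!r}; expected 'lr' or 'gbdt'")
    return res.predict(X_test)


@dataclass
class CVResult:
    """Per-fold metrics and reliability diagrams, plus mean ± SD."""

    model: str
    k: int
    folds: list[MetricSet]
    diagrams: list[ReliabilityDiagram]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.folds) != self.k:
            raise ValueError("fold count mismatch")
        if not self.mean:
            for name in _METRIC_NAMES:
                m, s = aggregate([getattr(f, name) for f in self.folds])
                self.mean[name], self.sd[name] = m, s

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, **f.as_dict()} for i, f in enumerate(self.folds)]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "folds": [f.as_dict() for f in self.folds],
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "sd_denominator": "n",
        }


def crossvalidate(
    cohort: CleanCohort,
    model: str = "lr",
    k: int = 5,
    n_bins: int = 10,
    seed: int = 0,
    gbdt_params: dict | None = None,
    tune_budget: int = 0,
    tuning: str = "once",
) -> CVResult:
    """Stratified k-fold evaluation of one model family.

    Each round fits on k-1 folds (logistic regression re-standardizes on
    its training portion every round) and computes ECE, Logloss, AUC and
    the reliability diagram on the held-out fold.  With ``tune_budget``
    > 0 the boosted model's hyperparameters are searched on the first
    round's training portion and reused (``tuning="once"``, default) or
    re-searched per round (``tuning="per_fold"``).
    """
    if tuning not in ("once", "per_fold"):
        raise ValueError("tuning must be 'once' or 'per_fold'")
    if model not in ("lr", "gbdt"):
        raise ValueError(f"unknown model {model!r}; expected 'lr' or 'gbdt'")
    assignment = stratified_kfold(cohort.y, k=k, seed=seed)
    folds: list[MetricSet] = []
    diagrams: list[ReliabilityDiagram] = []
    params = gbdt_params
    for fold in range(k):
        test_mask = assignment == fold
        X_tr = cohort.X[~test_mask].reset_index(drop=True)
        y_tr = cohort.y[~test_mask]
        X_te = cohort.X[test_mask].reset_index(drop=True)
        y_te = cohort.y[test_mask]
        if model == "gbdt" and tune_budget > 0 and (tuning == "per_fold" or fold == 0):
            space = HyperparameterSearchSpace(budget=tune_budget, seed=seed)
            tuned, _, _ = tune_gbdt(X_tr, y_tr, space=space)
            params = tuned
        try:
            p = _fit_predict(model, X_tr, y_tr, X_te, seed, params)
        except Exception as err:
            raise RuntimeError(f"model fit failed in CV fold {fold}: {err}") from err
        mset, diagram = compute_metrics(p, y_te, n_bins=n_bins)
        folds.append(mset)
        diagrams.append(diagram)
    return CVResult(model=model, k=k, folds=folds, diagrams=diagrams)


@dataclass
class SweepResult:
    """Learning-curve experiment output.

    ``records`` holds one row per (model, size, repeat) with the three
    metrics; ``aggregates`` the mean ± SD per cell; ``curves`` the
    reliability-diagram ensembles; ``test_index`` the common test rows.
    """

    records: pd.DataFrame
    aggregates: pd.DataFrame
    curves: dict[tuple[str, int], list[ReliabilityDiagram]]
    test_index: np.ndarray
    sizes: tuple[int, ...]
    repeats: int
    skipped: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_csv(self, records_path, aggregates_path=None) -> None:
        self.records.to_csv(records_path, index=False)
        if aggregates_path is not None:
            self.aggregates.to_csv(aggregates_path, index=False)


_RECORD_COLUMNS = ["model", "size", "repeat", "ece", "logloss", "auc",
                   "n_evaluated"]


def _aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        return pd.DataFrame(columns=["model", "size", "n_repeats"]
                            + [f"{m}_{s}" for m in _METRIC_NAMES
                               for s in ("mean", "sd")])
    rows = []
    for (model, size), grp in records.groupby(["model", "size"], sort=True):
        row = {"model": model, "size": size, "n_repeats": len(grp)}
        for name in _METRIC_NAMES:
            m, s = aggregate(grp[name])
            row[f"{name}_mean"], row[f"{name}_sd"] = m, s
        rows.append(row)
    return pd.DataFrame(rows)


def sample_size_sweep(
    cohort: CleanCohort,
    sizes,
    repeats: int = 100,
    test_fraction: float = 0.2,
    models: tuple[str, ...] = ("lr", "gbdt"),
    n_bins: int = 10,
    seed: int = 0,
    tune_budget: int = 0,
    stratify_subsamples: bool = False,
    keep_curves: bool = True,
) -> SweepResult:
    """Train on nested random subsamples, evaluate on one common test set.

    A single stratified ``test_fraction`` holdout is fixed up front; every
    (size, repeat) cell draws a simple random subsample without
    replacement from the remaining pool (optionally stratified), trains
    each model and scores it on the common test set.  Subsamples that end
    up single-class are skipped and logged.  Boosted-tree hyperparameters
    are searched once per size on the first repeat when ``tune_budget`` >
    0, then reused across that size's repeats.
    """
    sizes = tuple(int(s) for s in sizes)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    unknown = set(models) - {"lr", "gbdt"}
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    pool_idx, test_idx = train_test_split(
        np.arange(cohort.n), test_size=test_fraction,
        stratify=cohort.y, random_state=seed)
    pool_idx = np.sort(pool_idx)
    test_idx = np.sort(test_idx)
    too_big = [s for s in sizes if s > len(pool_idx)]
    if too_big:
        raise ValueError(
            f"requested training sizes {too_big} exceed the pool ({len(pool_idx)})")

    X_test = cohort.X.iloc[test_idx].reset_index(drop=True)
    y_test = cohort.y[test_idx]
    y_pool = cohort.y[pool_idx]

    root = np.random.SeedSequence(seed)
    draw_streams = root.spawn(len(sizes))

    rows, skipped = [], []
    curves: dict[tuple[str, int], list[ReliabilityDiagram]] = {
        (m, s): [] for m in models for s in sizes}
    gbdt_params_by_size: dict[int, dict | None] = {}

    for size, stream in zip(sizes, draw_streams):
        rng = np.random.default_rng(stream)
        for repeat in range(repeats):
            if stratify_subsamples:
                pos = pool_idx[y_pool == 1]
                neg = pool_idx[y_pool == 0]
                n_pos = int(round(size * len(pos) / len(pool_idx)))
                sub = np.concatenate([
                    rng.choice(pos, size=n_pos, replace=False),
                    rng.choice(neg, size=size - n_pos, replace=False)])
            else:
                sub = rng.choice(pool_idx, size=size, replace=False)
            y_sub = cohort.y[sub]
            if y_sub.min() == y_sub.max():
                skipped.append({"size": size, "repeat": repeat,
                                "reason": "single-class subsample"})
                continue
            X_sub = cohort.X.iloc[sub].reset_index(drop=True)
            for model in models:
                params = None
                if model == "gbdt":
                    if size not in gbdt_params_by_size:
                        if tune_budget > 0:
                            space = HyperparameterSearchSpace(
                                budget=tune_budget, seed=seed)
                            tuned, _, _ = tune_gbdt(X_sub, y_sub, space=space)
                            gbdt_params_by_size[size] = tuned
                        else:
                            gbdt_params_by_size[size] = None
                    params = gbdt_params_by_size[size]
                try:
                    p = _fit_predict(model, X_sub, y_sub, X_test, seed, params)
                except (ValueError, RuntimeError) as err:
                    # e.g. perfect separation on a tiny draw: drop the cell,
                    # keep the protocol running, report the count
                    skipped.append({"size": size, "repeat": repeat,
                                    "model": model, "reason": str(err)})
                    continue
                mset, diagram = compute_metrics(p, y_test, n_bins=n_bins)
                rows.append({"model": model, "size": size, "repeat": repeat,
                             **mset.as_dict()})
                if keep_curves:
                    curves[(model, size)].append(diagram)

    records = (pd.DataFrame(rows) if rows
               else pd.DataFrame(columns=_RECORD_COLUMNS))
    return SweepResult(
        records=records,
        aggregates=_aggregate_records(records),
        curves=curves,
        test_index=test_idx,
        sizes=sizes,
        repeats=repeats,
        skipped=skipped,
        meta={"seed": seed, "test_fraction": test_fraction,
              "tune_budget": tune_budget, "n_bins": n_bins,
              "sd_denominator": "n",
              "stratify_subsamples": stratify_subsamples},
    )
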