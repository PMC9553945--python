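"""Cohort CSV IO, figure rendering and the end-to-end pipeline driver.

The CSV dialect is deliberately plain: UTF-8, comma-separated, ``.``
decimal, header required, empty field = missing, sentinel codes written
literally.  Figures are derived artifacts only — every number they show is
also emitted as CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import CleanCohort, CleaningParams, clean_cohort
from .cohort import (
    CSV_COLUMNS,
    PREDICTOR_VARS,
    RawCohort,
    default_config,
    generate_cohort,
)
from .experiments import CVResult, SweepResult, crossvalidate, sample_size_sweep

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_clean_cohort",
    "write_clean_cohort",
    "render_cv_report",
    "render_sweep_report",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("calicohort")

_NUMERIC_BASELINE = [c for c in PREDICTOR_VARS if c != "UP"]
_NUMERIC_FOLLOWUP = ["followup_offset_days", "followup_FPG",
                     "followup_HbA1c", "followup_drug"]


def _parse_numeric(frame: pd.DataFrame, col: str, rows: np.ndarray) -> pd.Series:
    """Float conversion that names the offending cell on failure."""
    raw = frame[col].replace("", np.nan)
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unparseable value {raw.iloc[i]!r} in column {col!r}, "
            f"file row {int(rows[i]) + 2}")  # +2: header line and 1-based rows
    return out


def write_cohort(raw: RawCohort, path) -> None:
    raw.to_csv(path)


def read_cohort(path) -> RawCohort:
    """Strict reader for the raw cohort CSV (baseline + follow-up rows)."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    unknown = [c for c in table.columns if c not in CSV_COLUMNS]
    if missing or unknown:
        raise ValueError(f"cohort CSV schema mismatch: missing {missing}, unknown {unknown}")
    table = table[CSV_COLUMNS]  # header-driven: column order irrelevant

    kinds = set(table["record_type"])
    if not kinds <= {"baseline", "followup"}:
        raise ValueError(f"unknown record_type values: {sorted(kinds - {'baseline', 'followup'})}")

    base_rows = np.flatnonzero((table["record_type"] == "baseline").to_numpy())
    fup_rows = np.flatnonzero((table["record_type"] == "followup").to_numpy())
    base = table.iloc[base_rows].reset_index(drop=True)
    fup = table.iloc[fup_rows].reset_index(drop=True)

    baseline = pd.DataFrame({"id": _parse_numeric(base, "id", base_rows).astype(np.int64)})
    for col in _NUMERIC_BASELINE:
        baseline[col] = _parse_numeric(base, col, base_rows)
    baseline["UP"] = base["UP"].replace("", np.nan)
    baseline["diabetes_history"] = _parse_numeric(base, "diabetes_history", base_rows)
    baseline["inconsistent"] = (
        _parse_numeric(base, "inconsistent", base_rows).fillna(0).astype(np.int64))
    baseline = baseline[["id"] + PREDICTOR_VARS + ["diabetes_history", "inconsistent"]]

    followups = pd.DataFrame({"id": _parse_numeric(fup, "id", fup_rows).astype(np.int64)})
    for col in _NUMERIC_FOLLOWUP:
        followups[col] = _parse_numeric(fup, col, fup_rows)
    followups["followup_offset_days"] = followups["followup_offset_days"].astype(np.int64)
    followups["followup_drug"] = followups["followup_drug"].astype(np.int64)

    return RawCohort(baseline=baseline, followups=followups,
                     meta={"source": str(path), "n_rows": len(table)})


def write_clean_cohort(cohort: CleanCohort, path) -> None:
    out = cohort.X.copy()
    out["outcome"] = cohort.y
    out.to_csv(path, index=False)


def read_clean_cohort(path) -> CleanCohort:
    table = pd.read_csv(path)
    expected = PREDICTOR_VARS + ["outcome"]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"clean cohort CSV missing columns: {missing}")
    return CleanCohort(X=table[PREDICTOR_VARS], y=table["outcome"].to_numpy())


# ---------------------------------------------------------------------------
# figures and tables
# ---------------------------------------------------------------------------

def _diagram_band(diagrams):
    """Mean curve and SD band over an ensemble of diagrams (per bin).

    Bins empty in every fold stay NaN and are dropped by the caller.
    """
    import warnings as _warnings

    pred = np.vstack([d.mean_pred for d in diagrams])
    obs = np.vstack([d.frac_pos for d in diagrams])
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*(empty slice|[Dd]egrees of freedom).*")
        return (np.nanmean(pred, axis=0), np.nanmean(obs, axis=0),
                np.nanstd(obs, axis=0))


def render_cv_report(results: dict[str, CVResult], outdir) -> list[Path]:
    """Reliability diagram (fold curves + mean ± SD band) and metric tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no cross-validation results to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4.5),
                             squeeze=False)
    for ax, (name, cv) in zip(axes[0], results.items()):
        ax.plot([0, 1], [0, 1], color="0.6", lw=1, ls="--")
        for d in cv.diagrams:
            m = d.nonempty
            ax.plot(d.mean_pred[m], d.frac_pos[m], lw=0.7, alpha=0.6)
        mp, mo, so = _diagram_band(cv.diagrams)
        ok = ~np.isnan(mp)
        ax.plot(mp[ok], mo[ok], color="black", lw=2, label="mean of folds")
        ax.fill_between(mp[ok], (mo - so)[ok], (mo + so)[ok],
                        color="0.8", alpha=0.6, label="±1 SD")
        ax.set_title(f"{name} (k={cv.k})")
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("fraction of positives")
        ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig_path = outdir / "cv_reliability.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    written.append(fig_path)

    summary = {name: cv.to_dict() for name, cv in results.items()}
    json_path = outdir / "cv_metrics.json"
    json_path.write_text(json.dumps(summary, indent=2))
    written.append(json_path)
    for name, cv in results.items():
        p = outdir / f"cv_folds_{name}.csv"
        cv.to_frame().to_csv(p, index=False)
        written.append(p)
        for i, d in enumerate(cv.diagrams):
            dp = outdir / f"cv_diagram_{name}_fold{i}.csv"
            d.to_frame().to_csv(dp, index=False)
            written.append(dp)
    return written


def render_sweep_report(sweep: SweepResult, outdir) -> list[Path]:
    """Metric-vs-size curves with error bars, curve ensembles, CSV tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if sweep.records.empty:
        raise ValueError("empty sweep result")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    agg = sweep.aggregates

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for metric, ax in zip(("logloss", "ece", "auc"), axes):
        for model, grp in agg.groupby("model"):
            grp = grp.sort_values("size")
            ax.errorbar(grp["size"], grp[f"{metric}_mean"],
                        yerr=grp[f"{metric}_sd"], marker="o", capsize=3,
                        label=model)
        ax.set_xscale("log")
        ax.set_xlabel("training sample size")
        ax.set_ylabel(metric)
        ax.legend()
    fig.tight_layout()
    p = outdir / "sweep_metrics.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if sweep.curves and any(sweep.curves.values()):
        models = sorted({m for m, _ in sweep.curves})
        fig, axes = plt.subplots(len(models), len(sweep.sizes),
                                 figsize=(3.2 * len(sweep.sizes), 3.2 * len(models)),
                                 squeeze=False)
        for i, model in enumerate(models):
            for j, size in enumerate(sweep.sizes):
                ax = axes[i][j]
                ax.plot([0, 1], [0, 1], color="0.6", lw=1, ls="--")
                for d in sweep.curves.get((model, size), []):
                    m = d.nonempty
                    ax.plot(d.mean_pred[m], d.frac_pos[m], lw=0.5, alpha=0.25,
                            color="tab:blue")
                ax.set_title(f"{model}, n={size}", fontsize=9)
        fig.tight_layout()
        p = outdir / "sweep_reliability_ensembles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    records_path = outdir / "sweep_records.csv"
    agg_path = outdir / "sweep_aggregates.csv"
    sweep.to_csv(records_path, agg_path)
    written += [records_path, agg_path]
    return written


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "clean", "cv", "sweep", "report")


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    outdir: str
    n_participants: int = 20_000
    seed: int = 0
    nonlinear: bool = True
    pathologies: bool = True
    stages: tuple[str, ...] = _STAGES
    models: tuple[str, ...] = ("lr", "gbdt")
    k: int = 5
    n_bins: int = 10
    sweep_sizes: tuple[int, ...] = (1000, 2000, 4500)
    sweep_repeats: int = 10
    test_fraction: float = 0.2
    tune_budget: int = 0
    cleaning: CleaningParams = field(default_factory=CleaningParams)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, default=str)

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        cleaning = payload.pop("cleaning", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in payload.items()})
        if cleaning:
            cleaning["forced_drops"] = tuple(cleaning.get("forced_drops", ()))
            cleaning["sentinels"] = {k: tuple(v) for k, v in
                                     cleaning.get("sentinels", {}).items()}
            cfg.cleaning = CleaningParams(**cleaning)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns artifact paths.

    Any stage failure raises with the stage name attached; seeds, row
    counts and wall times are logged and recorded in ``meta.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage_log: list[dict] = []
    raw = clean = None
    cv_results: dict[str, CVResult] = {}
    sweep = None

    for stage in _STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                cfg = default_config(config.n_participants, seed=config.seed,
                                     nonlinear=config.nonlinear,
                                     pathologies=config.pathologies)
                raw = generate_cohort(cfg)
                path = outdir / "cohort.csv"
                write_cohort(raw, path)
                artifacts["cohort"] = path
                info = {"rows": raw.n_participants}
            elif stage == "clean":
                raw = raw if raw is not None else read_cohort(outdir / "cohort.csv")
                clean, report = clean_cohort(raw, config.cleaning)
                path = outdir / "clean.csv"
                write_clean_cohort(clean, path)
                rpath = outdir / "cleaning_report.json"
                rpath.write_text(json.dumps(report.to_dict(), indent=2))
                artifacts["clean"], artifacts["cleaning_report"] = path, rpath
                info = {"rows": clean.n, "prevalence": clean.prevalence}
            elif stage == "cv":
                clean = clean if clean is not None else read_clean_cohort(outdir / "clean.csv")
                for model in config.models:
                    cv_results[model] = crossvalidate(
                        clean, model=model, k=config.k, n_bins=config.n_bins,
                        seed=config.seed, tune_budget=config.tune_budget)
                info = {m: cv_results[m].mean for m in cv_results}
            elif stage == "sweep":
                clean = clean if clean is not None else read_clean_cohort(outdir / "clean.csv")
                sweep = sample_size_sweep(
                    clean, sizes=config.sweep_sizes, repeats=config.sweep_repeats,
                    test_fraction=config.test_fraction, models=config.models,
                    n_bins=config.n_bins, seed=config.seed,
                    tune_budget=config.tune_budget)
                info = {"cells": len(sweep.records)}
            else:  # report
                report_dir = outdir / "report"
                written = []
                if cv_results:
                    written += render_cv_report(cv_results, report_dir)
                if sweep is not None:
                    written += render_sweep_report(sweep, report_dir)
                artifacts["report"] = report_dir
                info = {"files": len(written)}
        except Exception as err:
            log.error("stage %s failed: %s", stage, err)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        dt = time.perf_counter() - t0
        log.info("stage %s done in %.2fs: %s", stage, dt, info)
        stage_log.append({"stage": stage, "seconds": round(dt, 3), **info})

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stage_log,
    }
    meta_path = outdir / "meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    artifacts["meta"] = meta_path
    return artifacts
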