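"""Calibration and discrimination metrics for binary risk predictions.

A model is *reliable* (well calibrated) when, among people assigned risk
near p, a fraction near p actually develops the outcome.  The reliability
diagram makes this visible: predictions are binned into M equal-width
probability intervals and the observed positive fraction of each bin is
plotted against its mean predicted probability; a perfectly calibrated
model lies on the diagonal.  The expected calibration error (ECE)
summarizes the diagram as the bin-count-weighted mean absolute gap

    ECE = sum_m (N_m / N) |ybar_m - pbar_m|.

Logloss (mean negative log-likelihood, nats) is the proper scoring rule
both models optimize; AUC measures pure discrimination via the
Mann-Whitney pair statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ReliabilityDiagram",
    "MetricSet",
    "assign_bins",
    "reliability_diagram",
    "ece",
    "logloss",
    "auc",
    "compute_metrics",
]

LOGLOSS_EPS = 1e-15  # probability clipping bound before taking logs


def _check_probabilities(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    bad = np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))
    if bad.size:
        raise ValueError(
            f"predicted probabilities outside [0, 1] at index {bad[0]}: {p[bad[0]]}")
    return p


def _check_outcomes(p: np.ndarray, y) -> np.ndarray:
    y = np.asarray(y)
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(y)} outcomes")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    return y.astype(np.int64)


def assign_bins(p, n_bins: int) -> np.ndarray:
    """Equal-width bin index (1-based) for each probability.

    Bin m covers [(m-1)/M, m/M) for m < M; the last bin is closed at 1 so
    p = 1 is assigned.  Edge ties go to the upper bin (half-open
    convention).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = _check_probabilities(p)
    idx = np.floor(p * n_bins).astype(np.int64)
    return np.minimum(idx, n_bins - 1) + 1


@dataclass
class ReliabilityDiagram:
    """Per-bin summary of predicted vs observed event frequency.

    Empty bins carry NaN for ``mean_pred`` and ``frac_pos`` and contribute
    nothing to the ECE.
    """

    n_bins: int
    edges: np.ndarray          # length n_bins + 1
    counts: np.ndarray         # N_m, length n_bins
    mean_pred: np.ndarray      # pbar_m (NaN when empty)
    frac_pos: np.ndarray       # ybar_m (NaN when empty)
    n_total: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("bin counts must sum to the total sample size")

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_index": np.arange(1, self.n_bins + 1),
            "lower_edge": self.edges[:-1],
            "upper_edge": self.edges[1:],
            "n": self.counts,
            "mean_predicted": self.mean_pred,
            "fraction_positive": self.frac_pos,
        })

    def plot(self, ax=None, **kwargs):
        """Reliability curve over nonempty bins, with the diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([0, 1], [0, 1], color="0.6", lw=1, ls="--")
        m = self.nonempty
        ax.plot(self.mean_pred[m], self.frac_pos[m], marker="o", **kwargs)
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("fraction of positives")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        return ax


def reliability_diagram(p, y, n_bins: int = 10) -> ReliabilityDiagram:
    """Bin predictions into M equal-width intervals and summarise each bin."""
    p = _check_probabilities(p)
    y = _check_outcomes(p, y)
    if len(p) == 0:
        raise ValueError("need at least one prediction")
    bins = assign_bins(p, n_bins) - 1
    counts = np.bincount(bins, minlength=n_bins)
    sum_p = np.bincount(bins, weights=p, minlength=n_bins)
    sum_y = np.bincount(bins, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pred = np.where(counts > 0, sum_p / np.maximum(counts, 1), np.nan)
        frac_pos = np.where(counts > 0, sum_y / np.maximum(counts, 1), np.nan)
    return ReliabilityDiagram(
        n_bins=n_bins,
        edges=np.linspace(0.0, 1.0, n_bins + 1),
        counts=counts,
        mean_pred=mean_pred,
        frac_pos=frac_pos,
        n_total=len(p),
    )


def ece(diagram: ReliabilityDiagram) -> float:
    """Expected calibration error of a reliability diagram."""
    m = diagram.nonempty
    w = diagram.counts[m] / diagram.n_total
    return float(np.sum(w * np.abs(diagram.frac_pos[m] - diagram.mean_pred[m])))


def logloss(p, y, eps: float = LOGLOSS_EPS) -> float:
    """Mean negative log-likelihood in nats, with probability clipping."""
    p = _check_probabilities(p)
    y = _check_outcomes(p, y)
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1 - y) * np.log1p(-pc)))


def auc(p, y) -> float:
    """ROC AUC as the tie-aware Mann-Whitney statistic.

    Equals (concordant pairs + half the tied pairs) / (n_pos * n_neg);
    identical to trapezoidal integration of the ROC curve.
    """
    p = _check_probabilities(p)
    y = _check_outcomes(p, y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: outcomes contain a single class")
    ranks = rankdata(p)  # midranks handle ties with 0.5 credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class MetricSet:
    """One evaluation: calibration (ece, logloss) and discrimination (auc)."""

    ece: float
    logloss: float
    auc: float
    n_evaluated: int

    def as_dict(self) -> dict[str, float]:
        return {"ece": self.ece, "logloss": self.logloss, "auc": self.auc,
                "n_evaluated": self.n_evaluated}


def compute_metrics(p, y, n_bins: int = 10) -> tuple[MetricSet, ReliabilityDiagram]:
    """All three metrics plus the reliability diagram for one prediction set."""
    diagram = reliability_diagram(p, y, n_bins)
    return MetricSet(
        ece=ece(diagram),
        logloss=logloss(p, y),
        auc=auc(p, y),
        n_evaluated=diagram.n_total,
    ), diagram
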