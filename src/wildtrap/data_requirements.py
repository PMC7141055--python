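"""Recall versus training-set size: how much data does a species need?

Per-class recall is grouped into bins by the number of training images
the class had (by default <500, 500–999, 1000+), each bin summarized by
its arithmetic mean and **population** standard deviation (divisor n).
A logarithmic least-squares fit ``recall = a + b·ln(n_train)`` over
500-image-wide groupings quantifies the trend, and a simple guideline
reads off the smallest bin whose mean recall clears a target — e.g.
that roughly 1,000+ images per class are needed for consistent 0.95
recall on the study this pipeline reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import ClassRecallRow

__all__ = [
    "RecallBinSummary",
    "LogFitResult",
    "bin_recall",
    "fit_log_regression",
    "binned_regression_points",
    "recall_curve_fit",
    "threshold_guideline",
]

DEFAULT_EDGES = (500, 1000)


@dataclass(frozen=True)
class RecallBinSummary:
    """One training-count bin: half-open ``[bin_low, bin_high)``; the
    last bin is unbounded (``bin_high`` is None).  ``sd_recall`` is the
    population SD and is exactly 0 for bins of at most one class."""

    bin_low: int
    bin_high: int | None
    n_classes: int
    mean_recall: float
    sd_recall: float

    def label(self) -> str:
        if self.bin_high is None:
            return f"{self.bin_low:,}+"
        return f"{self.bin_low}–{self.bin_high - 1}"


@dataclass(frozen=True)
class LogFitResult:
    """Least-squares fit of recall = a + b·ln(n_train)."""

    intercept: float
    slope: float
    r_squared: float


def _model_recalls(rows: Sequence[ClassRecallRow], model_name: str) -> np.ndarray:
    available = sorted({m for r in rows for m in r.recall_by_model})
    if any(model_name not in r.recall_by_model for r in rows):
        raise ValueError(f"model {model_name!r} not present in all rows; "
                         f"available models: {available}")
    return np.array([r.recall_by_model[model_name] for r in rows], dtype=float)


def bin_recall(rows: Sequence[ClassRecallRow], model_name: str,
               edges: Sequence[int] = DEFAULT_EDGES) -> list[RecallBinSummary]:
    """Group classes by training count into half-open bins bounded by
    ``edges`` (plus an implicit leading 0 and trailing +inf) and
    summarize the chosen model's recall per bin.

    Empty bins are reported with ``n_classes=0`` and zero mean/SD.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    recalls = _model_recalls(rows, model_name)
    n_train = np.array([r.n_train for r in rows])
    bounds = [0, *edges, None]
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_bin = (n_train >= lo) if hi is None else (n_train >= lo) & (n_train < hi)
        vals = recalls[in_bin]
        out.append(RecallBinSummary(
            bin_low=lo, bin_high=hi, n_classes=int(in_bin.sum()),
            mean_recall=float(vals.mean()) if vals.size else 0.0,
            sd_recall=float(vals.std()) if vals.size else 0.0,  # population SD
        ))
    return out


def fit_log_regression(points: Sequence[tuple[float, float]]) -> LogFitResult:
    """Ordinary least squares of recall on ln(n_train).

    ``r_squared = 1 - SS_res / SS_tot``; exactly collinear points in
    (ln n, recall) give r² = 1.  All n_train must be >= 1 and not all
    equal (the design would be degenerate).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    n = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if (n < 1).any():
        raise ValueError("all n_train must be >= 1")
    x = np.log(n)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all n_train equal")
    X = np.c_[np.ones_like(x), x]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return LogFitResult(intercept=float(beta[0]), slope=float(beta[1]),
                        r_squared=min(1.0, max(0.0, r2)))


def binned_regression_points(rows: Sequence[ClassRecallRow], model_name: str,
                             bin_width: int = 500) -> list[tuple[float, float]]:
    """Points for the recall-vs-data trend fit: classes are grouped into
    contiguous ``bin_width``-wide training-count bins; each non-empty
    bin contributes (mean n_train, mean recall)."""
    recalls = _model_recalls(rows, model_name)
    n_train = np.array([r.n_train for r in rows], dtype=float)
    points = []
    lo = 0.0
    top = n_train.max()
    while lo <= top:
        in_bin = (n_train >= lo) & (n_train < lo + bin_width)
        if in_bin.any():
            points.append((float(n_train[in_bin].mean()), float(recalls[in_bin].mean())))
        lo += bin_width
    return points


def recall_curve_fit(rows: Sequence[ClassRecallRow], model_name: str,
                     bin_width: int = 500) -> LogFitResult:
    """Logarithmic fit of the 500-wide-bin recall curve (see
    :func:`binned_regression_points`)."""
    return fit_log_regression(binned_regression_points(rows, model_name, bin_width))


def threshold_guideline(summaries: Sequence[RecallBinSummary],
                        target_recall: float) -> int | None:
    """Smallest bin lower bound whose (non-empty) bin mean recall meets
    the target, or None when no bin qualifies."""
    if not summaries:
        raise ValueError("no bin summaries given")
    qualifying = [s.bin_low for s in summaries
                  if s.n_classes > 0 and s.mean_recall >= target_recall]
    return min(qualifying) if qualifying else None
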