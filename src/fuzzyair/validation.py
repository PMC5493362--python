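"""Lagged validation of predictions against observed admission counts.

Exposure effects on respiratory admissions can appear on the same day
(lag 0) or on following days, so predictions made from day-*t* exposures are
scored against admissions on day *t + lag* for each requested lag.  Two
metrics are computed per lag:

* the Pearson product-moment correlation between predictions and observed
  counts, with a two-sided p-value from the t distribution (n - 2 df);
* the ROC area under the curve of predictions against dichotomized counts
  (positive = more than ``threshold`` daily admissions, default 2), with a
  Hanley-McNeil 95% confidence interval.

The AUC is the Mann-Whitney pair-counting estimator: the probability that a
randomly chosen high-admission day receives a higher prediction than a
randomly chosen low-admission day, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InvalidInputError,
    UndefinedCorrelationError,
    UndefinedROCError,
)

__all__ = [
    "LagResult",
    "ValidationReport",
    "lag_align",
    "pearson",
    "dichotomize",
    "roc_auc",
    "validate",
]


@dataclass(frozen=True)
class LagResult:
    """Metrics for one lag."""

    lag: int
    n: int
    pearson_r: float
    pearson_p: float
    auc: float
    auc_ci95: tuple[float, float]


@dataclass(frozen=True)
class ValidationReport:
    """Per-lag Pearson and ROC metrics, renderable as a table."""

    results: tuple[LagResult, ...]
    threshold: float

    def for_lag(self, lag: int) -> LagResult:
        for r in self.results:
            if r.lag == lag:
                return r
        raise KeyError(f"no result for lag {lag}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lag": [r.lag for r in self.results],
                "n": [r.n for r in self.results],
                "pearson_r": [r.pearson_r for r in self.results],
                "pearson_p": [r.pearson_p for r in self.results],
                "auc": [r.auc for r in self.results],
                "auc_ci_low": [r.auc_ci95[0] for r in self.results],
                "auc_ci_high": [r.auc_ci95[1] for r in self.results],
            }
        )

    def render(self) -> str:
        """Human-readable per-lag table (lag x metric with CIs)."""
        lines = [
            f"Validation report (positive = admissions > {self.threshold:g})",
            f"{'lag':>4} {'n':>5} {'r':>7} {'p':>9} {'AUC':>6} {'95% CI':>14}",
        ]
        for r in self.results:
            ci = f"({r.auc_ci95[0]:.2f}-{r.auc_ci95[1]:.2f})"
            lines.append(
                f"{r.lag:>4} {r.n:>5} {r.pearson_r:>7.3f} {r.pearson_p:>9.3g} "
                f"{r.auc:>6.3f} {ci:>14}")
        return "\n".join(lines)


def lag_align(predicted: Sequence[float], observed: Sequence[float],
              lag: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair prediction at day t with the observation at day t + lag.

    Both sequences must share the same (implicit) date index.  Pairs where
    either member is missing (NaN) are dropped.

    Returns
    -------
    (predicted_aligned, observed_aligned, n_dropped)
        The paired values and the number of pairs dropped for missingness
        (boundary loss from the lag itself is not counted as dropped).
    """
    lag = int(lag)
    if lag < 0:
        raise InvalidInputError(f"lag must be >= 0, got {lag}")
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("predicted and observed must be 1-d and aligned")
    n = x.size
    if lag >= n:
        raise InvalidInputError(f"lag {lag} >= series length {n}")
    xp = x[: n - lag] if lag else x
    yp = y[lag:] if lag else y
    keep = np.isfinite(xp) & np.isfinite(yp)
    return xp[keep], yp[keep], int((~keep).sum())


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t distribution, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: one series has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def dichotomize(observed: Sequence[float], threshold: float = 2
                ) -> np.ndarray:
    """Binary outcome labels: 1 where the count exceeds ``threshold``."""
    counts = np.asarray(observed, dtype=float)
    if np.any(counts < 0):
        raise InvalidInputError("admission counts must be non-negative")
    return (counts > threshold).astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney, ties count 1/2) with a Hanley-McNeil 95% CI.

    The standard error uses the Hanley-McNeil formula with
    Q1 = A / (2 - A) and Q2 = 2 A^2 / (1 + A); the interval is
    A +/- 1.96 SE, clamped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if set(np.unique(lab)) - {0, 1}:
        raise InvalidInputError(f"labels must be binary 0/1")
    n_pos = int(np.sum(lab == 1))
    n_neg = int(np.sum(lab == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(
            f"ROC undefined: {n_pos} positives, {n_neg} negatives")
    # Mann-Whitney via midranks: sum of positive ranks minus its minimum.
    ranks = stats.rankdata(s)
    auc = (ranks[lab == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auc = float(auc)
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
         + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return auc, (lo, hi)


def validate(predicted: Sequence[float], observed: Sequence[float],
             lags: Sequence[int] = (0, 1, 2),
             threshold: float = 2) -> ValidationReport:
    """Per-lag Pearson correlation and ROC AUC of predictions vs counts."""
    results = []
    for lag in lags:
        try:
            xp, yp, _ = lag_align(predicted, observed, lag)
            r, p = pearson(xp, yp)
            auc, ci = roc_auc(xp, dichotomize(yp, threshold))
        except (UndefinedCorrelationError, UndefinedROCError,
                InvalidInputError) as exc:
            raise type(exc)(f"lag {lag}: {exc}") from exc
        results.append(LagResult(
            lag=int(lag), n=int(xp.size), pearson_r=r, pearson_p=p,
            auc=auc, auc_ci95=ci))
    return ValidationReport(results=tuple(results), threshold=threshold)
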