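"""Pearson correlation of entropy removal with accuracy metrics.

Across a table of features the fraction of entropy removed is correlated
(two-tailed Pearson) with each conventional accuracy metric: Youden's J,
PPV, sensitivity, specificity, NPV and the (natural-)logged DOR.  Rows
with an undefined value for a given metric are excluded for that metric
only, so each correlation uses the largest defensible n.  No
multiple-comparison adjustment is applied; the analysis is descriptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, ValidationError

__all__ = ["METRICS", "MetricCorrelation", "CorrelationReport", "pearson", "correlation_report"]

#: Accuracy metrics correlated against er_fraction, in reporting order.
METRICS = ("youden_j", "ppv", "sensitivity", "specificity", "npv", "log_dor")


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Pearson correlation.

    Returns ``(r, p)`` where p comes from the t statistic
    ``r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.
    Requires length >= 3, finite values, and nonzero variance in both
    variables.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError(f"x and y must be equal-length vectors, got {xa.shape} vs {ya.shape}")
    if xa.size < 3:
        raise ValidationError(f"need at least 3 observations, got {xa.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("x and y must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateVarianceError("correlation undefined for a constant variable")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MetricCorrelation:
    metric: str
    r: float
    p_two_tailed: float
    n_used: int
    error: str | None = None

    @property
    def p_display(self) -> str:
        """p at full precision internally; below 1e-4 shown as '<0.0001'."""
        if self.error is not None:
            return "-"
        return "<0.0001" if self.p_two_tailed < 1e-4 else f"{self.p_two_tailed:.4f}"


@dataclass(frozen=True)
class CorrelationReport:
    """Per-metric Pearson r of er_fraction vs each accuracy metric."""

    metrics: dict[str, MetricCorrelation]
    excluded_rows: list[tuple[str, str, str]] = field(default_factory=list)
    n_table: int = 0

    def __getitem__(self, metric: str) -> MetricCorrelation:
        return self.metrics[metric]

    def to_dict(self) -> dict:
        return {
            "n_table": self.n_table,
            "metrics": {
                m: {
                    "r": c.r,
                    "p_two_tailed": c.p_two_tailed,
                    "n_used": c.n_used,
                    "error": c.error,
                }
                for m, c in self.metrics.items()
            },
            "excluded_rows": [list(t) for t in self.excluded_rows],
        }


def correlation_report(
    results: pd.DataFrame, metrics: Sequence[str] = METRICS
) -> CorrelationReport:
    """Correlate er_fraction with each accuracy metric over a results table.

    Exclusion is pairwise per metric: a row enters every correlation for
    which both er_fraction and that metric are finite.  Excluded rows
    are logged as ``(feature_id, metric, reason)``.  A metric whose
    usable column is constant (or shorter than 3) gets an error entry;
    the other metrics are unaffected.
    """
    if "er_fraction" not in results.columns:
        raise ValidationError("results table is missing the 'er_fraction' column")
    missing = [m for m in metrics if m not in results.columns]
    if missing:
        raise ValidationError(f"results table is missing metric columns: {missing}")

    ids = (
        results["feature_id"].astype(str)
        if "feature_id" in results.columns
        else results.index.astype(str)
    )
    er = pd.to_numeric(results["er_fraction"], errors="coerce")
    out: dict[str, MetricCorrelation] = {}
    excluded: list[tuple[str, str, str]] = []

    for metric in metrics:
        col = pd.to_numeric(results[metric], errors="coerce")
        er_ok = np.isfinite(er.to_numpy())
        col_ok = np.isfinite(col.to_numpy())
        usable = er_ok & col_ok
        for rid, e_ok, c_ok in zip(ids, er_ok, col_ok):
            if not (e_ok and c_ok):
                reason = "er_fraction undefined" if not e_ok else f"{metric} undefined"
                excluded.append((str(rid), metric, reason))
        x = er.to_numpy()[usable]
        y = col.to_numpy()[usable]
        try:
            r, p = pearson(x, y)
            out[metric] = MetricCorrelation(metric, r, p, int(usable.sum()))
        except (DegenerateVarianceError, ValidationError) as exc:
            out[metric] = MetricCorrelation(metric, math.nan, math.nan, int(usable.sum()), error=str(exc))

    return CorrelationReport(metrics=out, excluded_rows=excluded, n_table=len(results))
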