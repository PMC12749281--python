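"""2x2 contingency-table arithmetic for diagnostic tests.

A diagnostic feature applied to a cohort of ``N`` patients is summarised
either by its *performance parameters* (prevalence, sensitivity,
specificity, N) or by the four cells of the 2x2 table (TP, FP, FN, TN).
This module converts between the two representations and computes the
conventional accuracy metrics: sensitivity, specificity, PPV, NPV,
Youden's J and the diagnostic odds ratio (DOR).

Counts are kept as non-negative *reals*: tables derived from published
performance parameters are generally fractional, and every downstream
quantity (entropy, metrics) depends only on proportions, so nothing is
gained and precision is lost by rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import DegenerateMarginError, ValidationError

__all__ = [
    "TestPerformance",
    "DiagnosticCounts",
    "AccuracyMetrics",
    "derive_counts",
    "counts_to_performance",
    "accuracy_metrics",
]


def _check_proportion(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValidationError(f"{name} must be a finite number, got {value!r}")
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class TestPerformance:
    """Performance parameters of one feature in one disease context.

    Parameters
    ----------
    prevalence
        Proportion of the cohort with the target condition, in [0, 1].
    sensitivity
        P(test positive | disease), in [0, 1].
    specificity
        P(test negative | no disease), in [0, 1].
    n_total
        Cohort size N (> 0; need not be an integer).
    """

    __test__ = False  # keep pytest from collecting this as a test class

    prevalence: float
    sensitivity: float
    specificity: float
    n_total: float

    def __post_init__(self) -> None:
        _check_proportion("prevalence", self.prevalence)
        _check_proportion("sensitivity", self.sensitivity)
        _check_proportion("specificity", self.specificity)
        if not (
            isinstance(self.n_total, (int, float))
            and math.isfinite(self.n_total)
            and self.n_total > 0
        ):
            raise ValidationError(f"n_total must be > 0, got {self.n_total!r}")


@dataclass(frozen=True)
class DiagnosticCounts:
    """The four cells of a 2x2 diagnostic table (non-negative reals).

    Rows are the test result (positive = TP+FP, negative = FN+TN),
    columns the disease status (present = TP+FN, absent = FP+TN).
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be a finite number >= 0, got {v!r}")
        if self.total <= 0:
            raise ValidationError("table is empty: tp+fp+fn+tn must be > 0")

    @property
    def n_positive(self) -> float:
        """Number of test-positive patients (TP + FP)."""
        return self.tp + self.fp

    @property
    def n_negative(self) -> float:
        """Number of test-negative patients (FN + TN)."""
        return self.fn + self.tn

    @property
    def n_disease(self) -> float:
        """Number of patients with the condition (TP + FN)."""
        return self.tp + self.fn

    @property
    def n_healthy(self) -> float:
        """Number of patients without the condition (FP + TN)."""
        return self.fp + self.tn

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyMetrics:
    """Conventional 2x2 accuracy metrics for one feature.

    ``dor`` is the value downstream consumers should use: it equals the
    raw cross-product ratio TP*TN/(FP*FN) when all cells are positive and
    the Haldane-Anscombe corrected ratio (+0.5 on every cell, flagged by
    ``dor_corrected``) when any cell is zero.  ``dor_uncorrected`` keeps
    the raw value, with ``inf`` / ``0.0`` / ``nan`` sentinels where the
    ratio degenerates.  ``ppv`` / ``npv`` are ``nan`` when their test
    margin is empty (strict mode raises instead).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float
    dor: float
    log_dor: float
    dor_corrected: bool
    dor_uncorrected: float


def derive_counts(perf: TestPerformance) -> DiagnosticCounts:
    """Derive the 2x2 cells from prevalence, sensitivity, specificity and N.

    TP = prevalence * sensitivity * N
    FP = (1 - prevalence) * (1 - specificity) * N
    FN = prevalence * (1 - sensitivity) * N
    TN = (1 - prevalence) * specificity * N

    Cells are not rounded; the disease margin TP+FN = prevalence * N and
    the healthy margin FP+TN = (1 - prevalence) * N hold exactly up to
    float rounding.
    """
    p, se, sp, n = perf.prevalence, perf.sensitivity, perf.specificity, perf.n_total
    return DiagnosticCounts(
        tp=p * se * n,
        fp=(1.0 - p) * (1.0 - sp) * n,
        fn=p * (1.0 - se) * n,
        tn=(1.0 - p) * sp * n,
    )


def counts_to_performance(counts: DiagnosticCounts) -> TestPerformance:
    """Invert :func:`derive_counts`.

    Requires both disease margins to be non-empty; a table with no
    diseased (or no healthy) patients has no defined sensitivity
    (specificity).
    """
    if counts.n_disease <= 0:
        raise DegenerateMarginError("no diseased patients (tp + fn = 0): sensitivity undefined")
    if counts.n_healthy <= 0:
        raise DegenerateMarginError("no healthy patients (fp + tn = 0): specificity undefined")
    total = counts.total
    return TestPerformance(
        prevalence=counts.n_disease / total,
        sensitivity=counts.tp / counts.n_disease,
        specificity=counts.tn / counts.n_healthy,
        n_total=total,
    )


def accuracy_metrics(counts: DiagnosticCounts, *, strict: bool = True) -> AccuracyMetrics:
    """Compute sensitivity, specificity, PPV, NPV, Youden's J and the DOR.

    Youden's J = sensitivity + specificity - 1.  The DOR is
    TP*TN / (FP*FN); when any cell is exactly zero the reported ``dor``
    and ``log_dor`` (natural log) use the Haldane-Anscombe +0.5
    continuity correction on all four cells, with ``dor_corrected=True``
    and the raw sentinel kept in ``dor_uncorrected``.

    With ``strict=True`` an empty test margin (TP+FP = 0 or TN+FN = 0)
    raises; with ``strict=False`` the affected predictive value is
    ``nan``, which table-level consumers treat as "undefined for this
    row".
    """
    perf = counts_to_performance(counts)  # validates the disease margins
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn

    if tp + fp > 0:
        ppv = tp / (tp + fp)
    elif strict:
        raise DegenerateMarginError("no test-positive patients (tp + fp = 0): PPV undefined")
    else:
        ppv = math.nan
    if tn + fn > 0:
        npv = tn / (tn + fn)
    elif strict:
        raise DegenerateMarginError("no test-negative patients (tn + fn = 0): NPV undefined")
    else:
        npv = math.nan

    any_zero = min(tp, fp, fn, tn) == 0.0
    if not any_zero:
        dor_raw = (tp * tn) / (fp * fn)
        dor = dor_raw
        corrected = False
    else:
        if tp * tn == 0.0 and fp * fn == 0.0:
            dor_raw = math.nan  # 0/0: direction undetermined
        elif fp * fn == 0.0:
            dor_raw = math.inf
        else:
            dor_raw = 0.0
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
        corrected = True

    return AccuracyMetrics(
        sensitivity=perf.sensitivity,
        specificity=perf.specificity,
        ppv=ppv,
        npv=npv,
        youden_j=perf.sensitivity + perf.specificity - 1.0,
        dor=dor,
        log_dor=math.log(dor),
        dor_corrected=corrected,
        dor_uncorrected=dor_raw,
    )


def swap_test_labels(counts: DiagnosticCounts) -> DiagnosticCounts:
    """Relabel the test (call positives negative and vice versa).

    The rows of the table exchange: (tp, fp, fn, tn) -> (fn, tn, tp, fp).
    Under this swap Youden's J negates, the DOR inverts, and the entropy
    removed is unchanged.
    """
    return replace(counts, tp=counts.fn, fp=counts.tn, fn=counts.tp, tn=counts.fp)
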