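import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrodx import (
    AccuracyMetrics,
    DegenerateMarginError,
    DiagnosticCounts,
    TestPerformance,
    ValidationError,
    accuracy_metrics,
    counts_to_performance,
    derive_counts,
    swap_test_labels,
)

interior = st.floats(0.001, 0.999)


@pytest.mark.parametrize(
    "perf, expected",
    [
        ((0.5, 1.0, 1.0, 100), (50, 0, 0, 50)),
        ((0.2, 0.8, 0.9, 1000), (160, 80, 40, 720)),
        ((0.0, 0.7, 0.9, 100), (0, 10, 0, 90)),
    ],
)
def test_derive_counts_formulas(perf, expected):
    """TP/FP/FN/TN follow the prevalence-sensitivity-specificity product formulas."""
    c = derive_counts(TestPerformance(*perf))
    assert (c.tp, c.fp, c.fn, c.tn) == pytest.approx(expected, abs=1e-9)


def test_derive_counts_preserves_disease_margin():
    perf = TestPerformance(0.37, 0.61, 0.83, 517)
    c = derive_counts(perf)
    assert c.n_disease == pytest.approx(0.37 * 517, rel=1e-12)
    assert c.n_healthy == pytest.approx(0.63 * 517, rel=1e-12)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(prevalence=1.2, sensitivity=0.5, specificity=0.5, n_total=10), "prevalence"),
        (dict(prevalence=0.5, sensitivity=-0.1, specificity=0.5, n_total=10), "sensitivity"),
        (dict(prevalence=0.5, sensitivity=0.5, specificity=math.nan, n_total=10), "specificity"),
        (dict(prevalence=0.5, sensitivity=0.5, specificity=0.5, n_total=0), "n_total"),
    ],
)
def test_performance_validation_names_offending_field(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        TestPerformance(**kwargs)


def test_counts_validation():
    with pytest.raises(ValidationError):
        DiagnosticCounts(-1, 0, 0, 10)
    with pytest.raises(ValidationError):
        DiagnosticCounts(0, 0, 0, 0)


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((50, 0, 0, 50), (0.5, 1.0, 1.0, 100)),
        ((160, 80, 40, 720), (0.2, 0.8, 0.9, 1000)),
    ],
)
def test_counts_to_performance(counts, expected):
    p = counts_to_performance(DiagnosticCounts(*counts))
    assert (p.prevalence, p.sensitivity, p.specificity, p.n_total) == pytest.approx(expected)


def test_counts_to_performance_degenerate_margin():
    """Empty disease margins make sensitivity/specificity undefined."""
    with pytest.raises(DegenerateMarginError):
        counts_to_performance(DiagnosticCounts(0, 5, 0, 5))  # nobody diseased
    with pytest.raises(DegenerateMarginError):
        counts_to_performance(DiagnosticCounts(5, 0, 5, 0))  # nobody healthy
    # both disease margins non-empty: defined even with an empty test margin
    p = counts_to_performance(DiagnosticCounts(10, 5, 0, 0))
    assert p.sensitivity == 1.0 and p.specificity == 0.0


@settings(max_examples=300, derandomize=True)
@given(p=interior, se=interior, sp=interior, n=st.floats(1, 1e6))
def test_round_trip_performance_counts(p, se, sp, n):
    """derive_counts then counts_to_performance is the identity to 1e-9 relative."""
    perf = TestPerformance(p, se, sp, n)
    back = counts_to_performance(derive_counts(perf))
    assert back.prevalence == pytest.approx(p, rel=1e-9)
    assert back.sensitivity == pytest.approx(se, rel=1e-9)
    assert back.specificity == pytest.approx(sp, rel=1e-9)
    assert back.n_total == pytest.approx(n, rel=1e-9)


def test_worked_example_metrics(worked_counts):
    """Hand-arithmetic oracle: PPV=2/3, NPV=720/760, J=0.7, DOR=36."""
    m = accuracy_metrics(worked_counts)
    assert m.ppv == pytest.approx(2 / 3, rel=1e-12)
    assert m.npv == pytest.approx(720 / 760, rel=1e-12)
    assert m.youden_j == pytest.approx(0.7, abs=1e-12)
    assert m.dor == pytest.approx(36, rel=1e-12)
    assert m.log_dor == pytest.approx(math.log(36), rel=1e-12)
    assert not m.dor_corrected


def test_perfect_test_metrics():
    """Perfect test: J=1, raw DOR infinite, corrected DOR uses +0.5 on all cells."""
    m = accuracy_metrics(DiagnosticCounts(50, 0, 0, 50))
    assert m.youden_j == pytest.approx(1.0, abs=1e-12)
    assert m.dor_uncorrected == math.inf
    assert m.dor_corrected
    assert m.dor == pytest.approx((50.5 * 50.5) / (0.5 * 0.5), rel=1e-12)
    assert m.log_dor == pytest.approx(math.log(m.dor), rel=1e-12)


def test_independent_test_metrics():
    m = accuracy_metrics(DiagnosticCounts(25, 25, 25, 25))
    assert m.youden_j == pytest.approx(0.0, abs=1e-12)
    assert m.dor == pytest.approx(1.0, rel=1e-12)
    assert m.log_dor == pytest.approx(0.0, abs=1e-12)


def test_empty_test_margin_strict_vs_lenient():
    # sens=0, spec=1: nobody tests positive, PPV undefined
    c = derive_counts(TestPerformance(0.3, 0.0, 1.0, 100))
    with pytest.raises(DegenerateMarginError):
        accuracy_metrics(c)
    m = accuracy_metrics(c, strict=False)
    assert math.isnan(m.ppv)
    assert m.npv == pytest.approx(0.7, rel=1e-12)


@settings(max_examples=300, derandomize=True)
@given(
    tp=st.floats(0.5, 1e4), fp=st.floats(0.5, 1e4),
    fn=st.floats(0.5, 1e4), tn=st.floats(0.5, 1e4),
)
def test_label_swap_negates_j_and_inverts_dor(tp, fp, fn, tn):
    """Relabelling the test flips J's sign and inverts the odds ratio."""
    c = DiagnosticCounts(tp, fp, fn, tn)
    m = accuracy_metrics(c)
    ms = accuracy_metrics(swap_test_labels(c))
    assert ms.youden_j == pytest.approx(-m.youden_j, abs=1e-9)
    assert ms.dor * m.dor == pytest.approx(1.0, rel=1e-9)


@settings(max_examples=200, derandomize=True)
@given(p=interior, se=interior, sp=interior)
def test_youden_identity(p, se, sp):
    c = derive_counts(TestPerformance(p, se, sp, 1000))
    m = accuracy_metrics(c, strict=False)
    back = counts_to_performance(c)
    assert m.youden_j == pytest.approx(back.sensitivity + back.specificity - 1, abs=1e-12)


def test_metrics_is_frozen_dataclass(worked_counts):
    m = accuracy_metrics(worked_counts)
    assert isinstance(m, AccuracyMetrics)
    with pytest.raises(AttributeError):
        m.ppv = 0.5
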