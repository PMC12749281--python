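import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrodx import (
    DiagnosticCounts,
    TestPerformance,
    ValidationError,
    ZeroParentEntropyError,
    derive_counts,
    entropy_removal,
    mutual_information,
    shannon_entropy,
)

from conftest import reference_mutual_information

# frozen from the direct -0.2*log2(0.2) - 0.8*log2(0.8) evaluation
H_02_08 = 0.7219280948873623
# frozen from the brute-force MI oracle on (160, 80, 40, 720)
ER_BITS_WORKED = 0.2754581855356245
ER_FRACTION_WORKED = 0.3815590326604514


@pytest.mark.parametrize(
    "p, expected",
    [
        ((0.5, 0.5), 1.0),
        ((1.0, 0.0), 0.0),
        ((0.2, 0.8), H_02_08),
        ((0.25, 0.25, 0.25, 0.25), 2.0),
    ],
)
def test_shannon_entropy_values(p, expected):
    assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p", [(-0.1, 1.1), (0.5, 0.4), (0.6, 0.6)])
def test_shannon_entropy_rejects_bad_vectors(p):
    with pytest.raises(ValidationError):
        shannon_entropy(p)


def test_perfect_test_removes_all_entropy():
    r = entropy_removal(DiagnosticCounts(50, 0, 0, 50))
    assert r.er_fraction == pytest.approx(1.0, abs=1e-12)
    assert r.er_bits == pytest.approx(r.h_parent, abs=1e-12)
    assert r.h_positive == 0.0 and r.h_negative == 0.0


def test_independent_test_removes_nothing():
    r = entropy_removal(DiagnosticCounts(25, 25, 25, 25))
    assert r.er_bits == 0.0
    assert r.er_fraction == 0.0
    assert r.h_parent == pytest.approx(1.0, abs=1e-12)


def test_worked_example_entropy(worked_counts):
    """Frozen MI-oracle values for the (160, 80, 40, 720) table."""
    r = entropy_removal(worked_counts)
    assert r.h_parent == pytest.approx(H_02_08, abs=1e-12)
    assert r.er_bits == pytest.approx(ER_BITS_WORKED, abs=1e-12)
    assert r.er_fraction == pytest.approx(ER_FRACTION_WORKED, abs=1e-12)
    assert r.h_children_weighted == pytest.approx(
        (240 / 1000) * r.h_positive + (760 / 1000) * r.h_negative, abs=1e-12
    )


def test_zero_prevalence_errors():
    with pytest.raises(ZeroParentEntropyError):
        entropy_removal(DiagnosticCounts(0, 10, 0, 90))
    with pytest.raises(ZeroParentEntropyError):
        entropy_removal(DiagnosticCounts(10, 0, 90, 0))


@pytest.mark.parametrize(
    "joint, expected",
    [
        ((0.25, 0.25, 0.25, 0.25), 0.0),
        ((0.5, 0.0, 0.0, 0.5), 1.0),
        ((0.16, 0.08, 0.04, 0.72), ER_BITS_WORKED),
    ],
)
def test_mutual_information_values(joint, expected):
    assert mutual_information(joint) == pytest.approx(expected, abs=1e-12)


def test_mutual_information_rejects_bad_tables():
    with pytest.raises(ValidationError):
        mutual_information((0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValidationError):
        mutual_information((-0.1, 0.5, 0.3, 0.3))


def test_oracle_equivalence_bulk():
    """er_bits equals the 2x2 mutual information to <1e-10 over 10,000 random tables.

    Both package code paths (node-splitting vs joint-distribution) are
    additionally checked against the test-local brute-force formula.
    """
    rng = np.random.default_rng(42)
    tables = rng.uniform(0.01, 1000.0, size=(10_000, 4))
    worst = 0.0
    for tp, fp, fn, tn in tables:
        c = DiagnosticCounts(tp, fp, fn, tn)
        er = entropy_removal(c).er_bits
        mi_pkg = mutual_information(np.array([tp, fp, fn, tn]) / c.total)
        mi_ref = reference_mutual_information(tp, fp, fn, tn)
        worst = max(worst, abs(er - mi_pkg), abs(er - mi_ref))
    assert worst < 1e-10


@settings(max_examples=300, derandomize=True)
@given(
    tp=st.floats(0.01, 1e4), fp=st.floats(0.01, 1e4),
    fn=st.floats(0.01, 1e4), tn=st.floats(0.01, 1e4),
)
def test_er_bounds(tp, fp, fn, tn):
    """0 <= er_bits <= min(H(disease), H(test)); fraction in [0, 1]."""
    c = DiagnosticCounts(tp, fp, fn, tn)
    r = entropy_removal(c)
    h_test = shannon_entropy((c.n_positive / c.total, c.n_negative / c.total))
    assert 0.0 <= r.er_bits <= min(r.h_parent, h_test) + 1e-10
    assert 0.0 <= r.er_fraction <= 1.0
    assert r.h_parent <= 1.0 and r.h_positive <= 1.0 and r.h_negative <= 1.0


@settings(max_examples=200, derandomize=True)
@given(
    tp=st.floats(0.01, 1e4), fp=st.floats(0.01, 1e4),
    fn=st.floats(0.01, 1e4), tn=st.floats(0.01, 1e4),
)
def test_label_swap_leaves_er_unchanged(tp, fp, fn, tn):
    a = entropy_removal(DiagnosticCounts(tp, fp, fn, tn))
    b = entropy_removal(DiagnosticCounts(fn, tn, tp, fp))
    assert a.er_bits == pytest.approx(b.er_bits, abs=1e-10)
    assert a.er_fraction == pytest.approx(b.er_fraction, abs=1e-10)


def test_er_fraction_base_invariance(worked_counts):
    """The fraction removed is the same whether entropies use log2 or ln."""
    c = worked_counts

    def h_nats(a, b):
        n = a + b
        out = 0.0
        for v in (a, b):
            if v > 0:
                out -= (v / n) * math.log(v / n)
        return out

    h_parent = h_nats(c.n_disease, c.n_healthy)
    h_children = (
        c.n_positive * h_nats(c.tp, c.fp) + c.n_negative * h_nats(c.fn, c.tn)
    ) / c.total
    frac_nats = (h_parent - h_children) / h_parent
    assert entropy_removal(c).er_fraction == pytest.approx(frac_nats, abs=1e-12)


def test_er_zero_iff_independent_grid():
    """ER vanishes exactly when sensitivity = 1 - specificity."""
    for p in (0.05, 0.2, 0.5):
        for se in (0.1, 0.4, 0.75, 0.9):
            indep = derive_counts(TestPerformance(p, se, 1 - se, 1000))
            assert entropy_removal(indep).er_bits < 1e-12
            dep = derive_counts(TestPerformance(p, se, min(1 - se + 0.1, 1.0), 1000))
            assert entropy_removal(dep).er_bits > 1e-6
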