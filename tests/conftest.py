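import math

import pytest

from entrodx import DiagnosticCounts, SynthConfig, evaluate_table, generate_cohort


def reference_mutual_information(tp, fp, fn, tn):
    """Test-local brute-force mutual information (bits) of a 2x2 count table.

    Written directly from the definition, independent of every code path
    in the package, so it can arbitrate between them.
    """
    total = tp + fp + fn + tn
    cells = [(tp, tp + fp, tp + fn), (fp, tp + fp, fp + tn),
             (fn, fn + tn, tp + fn), (tn, fn + tn, fp + tn)]
    mi = 0.0
    for cell, row, col in cells:
        if cell > 0:
            mi += (cell / total) * math.log2(cell * total / (row * col))
    return mi


@pytest.fixture
def worked_counts():
    """The worked example: prevalence 0.2, sensitivity 0.8, specificity 0.9, N=1000."""
    return DiagnosticCounts(tp=160, fp=80, fn=40, tn=720)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 405-feature synthetic cohort with planted controls."""
    return generate_cohort(SynthConfig(seed=20260923))


@pytest.fixture(scope="session")
def default_results(default_cohort):
    ev = evaluate_table(default_cohort)
    assert not ev.failures
    return ev.results
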