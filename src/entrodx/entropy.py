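"""Shannon entropy and entropy removal on 2x2 diagnostic tables.

The whole cohort is the *parent node* of a one-level decision tree; the
test splits it into a test-positive child (TP + FP patients) and a
test-negative child (FN + TN patients).  The entropy removed by the
feature is the parent's disease/no-disease entropy minus the
case-weighted mean of the children's entropies — i.e. the information
the test result carries about disease status.  It equals the mutual
information between the test and disease indicators, which this module
also computes directly (from the joint distribution, a separate code
path) as a cross-check.

Entropies are in bits (base 2, the decision-tree convention); the
*fraction* of parent entropy removed is base-invariant and is the
quantity all downstream consumers (quadrants, correlations) use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .contingency import DiagnosticCounts
from .exceptions import ValidationError, ZeroParentEntropyError

__all__ = ["EntropyResult", "shannon_entropy", "entropy_removal", "mutual_information"]

_SUM_TOL = 1e-9
#: float-cancellation guard: information gain is provably >= 0, so tiny
#: negative er_bits are clamped to zero below this magnitude.
_CLAMP = 1e-12


@dataclass(frozen=True)
class EntropyResult:
    """Entropy bookkeeping for one feature.

    Attributes
    ----------
    h_parent
        Disease/no-disease entropy of the whole cohort, bits (<= 1).
    h_positive, h_negative
        Disease-status entropy within the test-positive and
        test-negative children, bits.  An empty child has entropy 0.
    h_children_weighted
        (n_positive * h_positive + n_negative * h_negative) / N, bits.
    er_bits
        Entropy removed, ``h_parent - h_children_weighted`` (>= 0).
    er_fraction
        ``er_bits / h_parent``, in [0, 1].  The headline quantity;
        multiply by 100 for the percentage of removed entropy.
    """

    h_parent: float
    h_positive: float
    h_negative: float
    h_children_weighted: float
    er_bits: float
    er_fraction: float


def shannon_entropy(p: Sequence[float], base: float = 2.0) -> float:
    """Shannon entropy -sum(p * log(p)) of a probability vector.

    ``p`` must be non-negative and sum to 1 within 1e-9; ``0 * log 0``
    contributes 0.  Returns bits by default.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("p must be a non-empty 1-d probability vector")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("p contains non-finite components")
    if np.any(arr < 0):
        raise ValidationError(f"p contains negative components: {arr.tolist()}")
    s = float(arr.sum())
    if abs(s - 1.0) > _SUM_TOL:
        raise ValidationError(f"p must sum to 1 within {_SUM_TOL}, got {s!r}")
    return float(_scipy_entropy(arr, base=base))


def _binary_entropy_from_counts(a: float, b: float) -> float:
    """Entropy in bits of the two-outcome split (a, b); 0 for an empty node."""
    n = a + b
    if n == 0:
        return 0.0
    return shannon_entropy((a / n, b / n))


def entropy_removal(counts: DiagnosticCounts) -> EntropyResult:
    """Entropy removed by one diagnostic feature.

    Parent entropy is taken over the (disease, no-disease) proportions
    of the whole cohort; child entropies over (TP, FP) within the
    test-positives and (FN, TN) within the test-negatives, weighted by
    child size.  Requires prevalence strictly inside (0, 1): at
    prevalence 0 or 1 the parent has no uncertainty and the fraction
    removed is undefined.
    """
    if counts.n_disease <= 0 or counts.n_healthy <= 0:
        raise ZeroParentEntropyError(
            "prevalence is 0 or 1: parent entropy is zero and the "
            "entropy-removal fraction is undefined"
        )
    total = counts.total
    h_parent = _binary_entropy_from_counts(counts.n_disease, counts.n_healthy)
    h_pos = _binary_entropy_from_counts(counts.tp, counts.fp)
    h_neg = _binary_entropy_from_counts(counts.fn, counts.tn)
    h_children = (counts.n_positive * h_pos + counts.n_negative * h_neg) / total
    er_bits = h_parent - h_children
    if er_bits < 0:
        if er_bits < -_CLAMP:
            raise AssertionError(f"negative information gain {er_bits!r}: numerical bug")
        er_bits = 0.0
    er_fraction = er_bits / h_parent
    return EntropyResult(
        h_parent=h_parent,
        h_positive=h_pos,
        h_negative=h_neg,
        h_children_weighted=h_children,
        er_bits=er_bits,
        er_fraction=min(er_fraction, 1.0),
    )


def mutual_information(joint) -> float:
    """Mutual information (bits) of a 2x2 joint probability table.

    ``joint`` is any array-like reshapeable to 2x2, non-negative,
    summing to 1 within 1e-9; rows index the test result and columns the
    disease status.  Computed directly as
    ``sum p(x,y) log2[p(x,y) / (p(x) p(y))]`` with zero cells dropped —
    deliberately *not* via :func:`entropy_removal`, so the two routes
    can check each other.
    """
    arr = np.asarray(joint, dtype=float).reshape(2, 2)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValidationError("joint table must be finite and non-negative")
    s = float(arr.sum())
    if abs(s - 1.0) > _SUM_TOL:
        raise ValidationError(f"joint table must sum to 1 within {_SUM_TOL}, got {s!r}")
    px = arr.sum(axis=1)
    py = arr.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            p = arr[i, j]
            if p > 0:
                mi += p * math.log2(p / (px[i] * py[j]))
    return max(mi, 0.0)
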