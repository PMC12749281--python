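"""Accuracy-vs-information quadrant classification.

Each feature is placed on two axes: Youden's J (accuracy) and the
fraction of parent entropy removed (information).  Inclusive threshold
cuts — by default J >= 0.60 for high accuracy and ER >= 0.40 for high
information — partition the plane into four quadrants of diagnostic
practicality.
"""

from __future__ import annotations

import enum
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "Quadrant",
    "QuadrantSummary",
    "CATEGORIES",
    "canonical_category",
    "classify",
    "summarize",
    "DEFAULT_J_CUT",
    "DEFAULT_ER_CUT",
]

DEFAULT_J_CUT = 0.60
DEFAULT_ER_CUT = 0.40

#: Canonical feature-category vocabulary; anything else tallies as Other.
CATEGORIES = ("Demographics", "Imaging", "Lab/Diagnostic Tests", "Signs/Symptoms/History")
OTHER_CATEGORY = "Other"

_CATEGORY_LOOKUP = {c.lower(): c for c in CATEGORIES}
# tolerated spellings seen in hand-curated tables
_CATEGORY_LOOKUP.update(
    {
        "demographic": "Demographics",
        "demo": "Demographics",
        "lab": "Lab/Diagnostic Tests",
        "laboratory": "Lab/Diagnostic Tests",
        "lab/diagnostic test": "Lab/Diagnostic Tests",
        "lab tests": "Lab/Diagnostic Tests",
        "laboratory tests": "Lab/Diagnostic Tests",
        "signs/symptoms": "Signs/Symptoms/History",
        "symptoms": "Signs/Symptoms/History",
        "signs": "Signs/Symptoms/History",
        "history": "Signs/Symptoms/History",
    }
)


class Quadrant(str, enum.Enum):
    HIGH_ACC_HIGH_INFO = "HIGH_ACC_HIGH_INFO"
    HIGH_ACC_LOW_INFO = "HIGH_ACC_LOW_INFO"
    LOW_ACC_HIGH_INFO = "LOW_ACC_HIGH_INFO"
    LOW_ACC_LOW_INFO = "LOW_ACC_LOW_INFO"


def canonical_category(raw: str | None, *, warn: bool = True) -> str:
    """Map a free-text category to the canonical vocabulary (case-insensitive).

    Unknown values are preserved by the caller but tallied as Other.
    """
    if raw is None:
        return OTHER_CATEGORY
    key = str(raw).strip().lower()
    if not key:
        return OTHER_CATEGORY
    hit = _CATEGORY_LOOKUP.get(key)
    if hit is None:
        if warn:
            warnings.warn(f"unknown feature category {raw!r}: tallied under 'Other'")
        return OTHER_CATEGORY
    return hit


def classify(
    j: float,
    er_fraction: float,
    j_cut: float = DEFAULT_J_CUT,
    er_cut: float = DEFAULT_ER_CUT,
) -> Quadrant:
    """Assign a (J, ER-fraction) pair to its quadrant.

    Both thresholds are inclusive on the "high" side: J >= j_cut means
    high accuracy, ER >= er_cut means high information.
    """
    if any(isinstance(v, float) and math.isnan(v) for v in (j, er_fraction, j_cut, er_cut)):
        raise ValidationError("classify received NaN input")
    if not -1.0 <= j <= 1.0:
        raise ValidationError(f"youden_j must lie in [-1, 1], got {j!r}")
    if not 0.0 <= er_fraction <= 1.0:
        raise ValidationError(f"er_fraction must lie in [0, 1], got {er_fraction!r}")
    high_acc = j >= j_cut
    high_info = er_fraction >= er_cut
    if high_acc:
        return Quadrant.HIGH_ACC_HIGH_INFO if high_info else Quadrant.HIGH_ACC_LOW_INFO
    return Quadrant.LOW_ACC_HIGH_INFO if high_info else Quadrant.LOW_ACC_LOW_INFO


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant and category tallies for a results table."""

    quadrant_counts: Mapping[str, int]
    category_counts: Mapping[str, int]
    j_cut: float
    er_cut: float
    n_rows: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "j_cut": self.j_cut,
            "er_cut": self.er_cut,
            "n_rows": self.n_rows,
            "quadrant_counts": dict(self.quadrant_counts),
            "category_counts": dict(self.category_counts),
        }


def summarize(
    results: pd.DataFrame,
    j_cut: float = DEFAULT_J_CUT,
    er_cut: float = DEFAULT_ER_CUT,
) -> QuadrantSummary:
    """Tally quadrant membership and category counts over a results table.

    ``results`` needs ``youden_j`` and ``er_fraction`` columns (and
    optionally ``category``); rows with missing values are rejected with
    their ids listed.
    """
    for col in ("youden_j", "er_fraction"):
        if col not in results.columns:
            raise ValidationError(f"results table is missing the {col!r} column")
    bad = results.index[
        results["youden_j"].isna() | results["er_fraction"].isna()
    ].tolist()
    if bad:
        ids = (
            results.loc[bad, "feature_id"].tolist()
            if "feature_id" in results.columns
            else bad
        )
        raise ValidationError(f"rows missing computed J/ER: {ids}")

    quad_counts = Counter({q.value: 0 for q in Quadrant})
    for j, er in zip(results["youden_j"], results["er_fraction"]):
        quad_counts[classify(float(j), float(er), j_cut, er_cut).value] += 1

    cat_counts = Counter({c: 0 for c in CATEGORIES})
    if "category" in results.columns:
        for raw in results["category"]:
            cat_counts[canonical_category(raw, warn=False)] += 1
    else:
        cat_counts[OTHER_CATEGORY] = len(results)

    return QuadrantSummary(
        quadrant_counts=dict(quad_counts),
        category_counts=dict(cat_counts),
        j_cut=j_cut,
        er_cut=er_cut,
        n_rows=len(results),
    )
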