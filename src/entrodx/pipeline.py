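"""Table-level evaluation: counts -> metrics -> entropy -> quadrant.

Glue between the per-feature computations and the tabular I/O: evaluate
every record of a :class:`~entrodx.io.FeatureTable` and collect the
results into a :class:`pandas.DataFrame` with the canonical result
columns.  Rows that cannot be evaluated (e.g. prevalence 0 or 1, where
the entropy-removal fraction is undefined) are reported as failures and
the run continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .contingency import accuracy_metrics, counts_to_performance
from .entropy import entropy_removal
from .exceptions import EntrodxError
from .io import RESULT_COLUMNS, FeatureRecord, FeatureTable
from .quadrant import DEFAULT_ER_CUT, DEFAULT_J_CUT, classify

__all__ = ["EvaluationResult", "evaluate_record", "evaluate_table"]


@dataclass
class EvaluationResult:
    """Evaluated table plus the rows that could not be evaluated."""

    results: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)


def evaluate_record(
    rec: FeatureRecord,
    j_cut: float = DEFAULT_J_CUT,
    er_cut: float = DEFAULT_ER_CUT,
) -> dict:
    """Evaluate one feature: all accuracy metrics, entropy removal, quadrant."""
    counts = rec.counts()
    perf = counts_to_performance(counts)
    acc = accuracy_metrics(counts, strict=False)
    ent = entropy_removal(counts)
    quad = classify(acc.youden_j, ent.er_fraction, j_cut, er_cut)
    return {
        "feature_id": rec.feature_id,
        "feature_name": rec.feature_name,
        "disease": rec.disease,
        "category": rec.category,
        "source": rec.source,
        "n_total": perf.n_total,
        "prevalence": perf.prevalence,
        "sensitivity": acc.sensitivity,
        "specificity": acc.specificity,
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "tn": counts.tn,
        "ppv": acc.ppv,
        "npv": acc.npv,
        "youden_j": acc.youden_j,
        "dor": acc.dor,
        "log_dor": acc.log_dor,
        "dor_corrected": acc.dor_corrected,
        "h_parent_bits": ent.h_parent,
        "er_bits": ent.er_bits,
        "er_fraction": ent.er_fraction,
        "quadrant": quad.value,
    }


def evaluate_table(
    table: FeatureTable,
    j_cut: float = DEFAULT_J_CUT,
    er_cut: float = DEFAULT_ER_CUT,
) -> EvaluationResult:
    """Evaluate every record; collect per-row failures instead of aborting."""
    rows: list[dict] = []
    failures: list[tuple[str, str]] = []
    for rec in table:
        try:
            rows.append(evaluate_record(rec, j_cut, er_cut))
        except EntrodxError as exc:
            failures.append((rec.feature_id, str(exc)))
    columns = list(RESULT_COLUMNS) + ["dor_corrected"]
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return EvaluationResult(results=df, failures=failures)
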