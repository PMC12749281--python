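"""CSV ingestion and serialization of feature tables.

A feature table is a CSV with one row per clinical feature per disease
context.  Each row carries metadata (feature name, disease, category,
source) and *either* the four raw counts (tp, fp, fn, tn) *or* the four
performance parameters (prevalence, sensitivity, specificity, n_total),
or both.  Headers are matched case-insensitively through an alias map
(extendable via a user-supplied column-mapping file), percentages with a
trailing ``%`` are divided by 100, and empty cells / ``NA`` are missing.

When a row carries both representations they are cross-checked at 1e-6
relative after deriving counts from the performance parameters; on
mismatch a warning is issued and the counts win — counts are the primary
observable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .contingency import DiagnosticCounts, TestPerformance, derive_counts
from .exceptions import SchemaError, ValidationError
from .quadrant import canonical_category

__all__ = [
    "FeatureRecord",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "write_results",
    "RESULT_COLUMNS",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: canonical column -> accepted header spellings (all compared lowercase)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "feature_id": ("feature_id", "id", "row_id", "row"),
    "feature_name": ("feature_name", "feature", "name", "finding", "symptom", "test"),
    "disease": ("disease", "condition", "diagnosis", "target", "target condition"),
    "category": ("category", "type", "feature type", "feature_category"),
    "source": ("source", "review", "citation", "reference", "study"),
    "tp": ("tp", "true_positives", "true positives"),
    "fp": ("fp", "false_positives", "false positives"),
    "fn": ("fn", "false_negatives", "false negatives"),
    "tn": ("tn", "true_negatives", "true negatives"),
    "prevalence": ("prevalence", "prev", "pretest probability"),
    "sensitivity": ("sensitivity", "sens", "sen"),
    "specificity": ("specificity", "spec", "spe"),
    "n_total": ("n_total", "n", "total", "total_patients", "total patients", "population"),
    "er_fraction_true": ("er_fraction_true",),
    "planted": ("planted",),
}

COUNT_FIELDS = ("tp", "fp", "fn", "tn")
PERF_FIELDS = ("prevalence", "sensitivity", "specificity", "n_total")
META_FIELDS = ("feature_id", "feature_name", "disease", "category", "source")

#: exact output column order of write_results
RESULT_COLUMNS = (
    "feature_id", "feature_name", "disease", "category", "source",
    "n_total", "prevalence", "sensitivity", "specificity",
    "tp", "fp", "fn", "tn",
    "ppv", "npv", "youden_j", "dor", "log_dor",
    "h_parent_bits", "er_bits", "er_fraction", "quadrant",
)

_CROSSCHECK_RTOL = 1e-6


@dataclass(frozen=True)
class FeatureRecord:
    """One clinical feature in one disease context."""

    feature_id: str
    feature_name: str
    disease: str = ""
    category: str = "Other"
    source: str = ""
    tp: float | None = None
    fp: float | None = None
    fn: float | None = None
    tn: float | None = None
    prevalence: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    n_total: float | None = None
    ground_truth: dict | None = None

    @property
    def has_counts(self) -> bool:
        return all(getattr(self, f) is not None for f in COUNT_FIELDS)

    @property
    def has_performance(self) -> bool:
        return all(getattr(self, f) is not None for f in PERF_FIELDS)

    def __post_init__(self) -> None:
        if not self.has_counts and not self.has_performance:
            missing_c = [f for f in COUNT_FIELDS if getattr(self, f) is None]
            missing_p = [f for f in PERF_FIELDS if getattr(self, f) is None]
            raise ValidationError(
                f"record {self.feature_id!r} carries neither a complete counts quartet "
                f"(missing {missing_c}) nor a complete performance quartet (missing {missing_p})"
            )
        if self.has_counts and self.has_performance:
            derived = derive_counts(
                TestPerformance(self.prevalence, self.sensitivity, self.specificity, self.n_total)
            )
            stated = (self.tp, self.fp, self.fn, self.tn)
            ref = (derived.tp, derived.fp, derived.fn, derived.tn)
            scale = max(max(abs(v) for v in ref), 1.0)
            if any(abs(a - b) > _CROSSCHECK_RTOL * scale for a, b in zip(stated, ref)):
                warnings.warn(
                    f"record {self.feature_id!r}: counts and performance parameters disagree "
                    f"beyond {_CROSSCHECK_RTOL} relative (counts {stated}, derived {ref}); "
                    "counts take precedence"
                )

    def counts(self) -> DiagnosticCounts:
        """Resolve the 2x2 table; stated counts win over derived ones."""
        if self.has_counts:
            return DiagnosticCounts(self.tp, self.fp, self.fn, self.tn)
        return derive_counts(
            TestPerformance(self.prevalence, self.sensitivity, self.specificity, self.n_total)
        )


@dataclass
class FeatureTable:
    """Ordered collection of feature records with provenance."""

    records: list[FeatureRecord]
    source_file: str | None = None
    read_at: str | None = None
    schema_version: str = SCHEMA_VERSION
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.feature_id in seen:
                raise ValidationError(f"duplicate feature_id {rec.feature_id!r} in table")
            seen.add(rec.feature_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FeatureRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> FeatureRecord:
        return self.records[i]


def _build_header_map(columns, extra_map: dict[str, str] | None) -> dict[str, str]:
    """Map canonical field -> actual CSV header present in this file."""
    lookup: dict[str, str] = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for a in aliases:
            lookup[a] = canon
    if extra_map:
        for src, canon in extra_map.items():
            if canon not in COLUMN_ALIASES:
                raise SchemaError(f"column map targets unknown field {canon!r}")
            lookup[src.strip().lower()] = canon
    out: dict[str, str] = {}
    for col in columns:
        canon = lookup.get(str(col).strip().lower())
        if canon is not None and canon not in out:
            out[canon] = col
    return out


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a flat ``header=field`` mapping file (one pair per line, # comments)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'csv_header=field', got {line!r}")
        src, canon = (part.strip() for part in line.split("=", 1))
        mapping[src] = canon
    return mapping


def _parse_number(raw) -> float | None:
    """Parse a cell: empty/NA -> None; trailing % -> divided by 100."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.upper() in {"NA", "NAN", "N/A"}:
        return None
    pct = s.endswith("%")
    if pct:
        s = s[:-1].strip()
    try:
        v = float(s)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number from {raw!r}") from exc
    return v / 100.0 if pct else v


def read_feature_table(
    path: str | Path,
    column_map: dict[str, str] | str | Path | None = None,
    *,
    strict: bool = True,
) -> FeatureTable:
    """Read a feature-table CSV.

    ``column_map`` may be a ``{csv_header: canonical_field}`` dict or the
    path of a flat ``header=field`` file, for tables whose headers the
    built-in alias map does not know.  With ``strict=False`` invalid rows
    are collected in ``table.rejects`` as ``(row_number, reason)`` instead
    of aborting the read (row numbers are 1-based data rows).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if isinstance(column_map, (str, Path)):
        column_map = load_column_map(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")
    header_map = _build_header_map(df.columns, column_map)

    if "feature_name" not in header_map:
        raise SchemaError(
            f"{path}: no feature-name column found; headers present: {list(df.columns)}; "
            f"accepted aliases: {COLUMN_ALIASES['feature_name']}"
        )
    have_counts_cols = all(f in header_map for f in COUNT_FIELDS)
    have_perf_cols = all(f in header_map for f in PERF_FIELDS)
    if not have_counts_cols and not have_perf_cols:
        raise SchemaError(
            f"{path}: neither a complete counts quartet {COUNT_FIELDS} nor a complete "
            f"performance quartet {PERF_FIELDS} is present; recognized columns: "
            f"{sorted(header_map)}"
        )

    records: list[FeatureRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        rowd = dict(zip(df.columns, row))

        def cell(field: str):
            col = header_map.get(field)
            return rowd.get(col) if col is not None else None

        try:
            numeric = {
                f: _parse_number(cell(f)) for f in (*COUNT_FIELDS, *PERF_FIELDS)
            }
            gt_er = _parse_number(cell("er_fraction_true")) if "er_fraction_true" in header_map else None
            planted = str(cell("planted") or "").strip() if "planted" in header_map else ""
            ground_truth = None
            if gt_er is not None or planted:
                ground_truth = {"er_fraction": gt_er, "planted": planted}
            fid = str(cell("feature_id") or "").strip() or f"row{i:04d}"
            rec = FeatureRecord(
                feature_id=fid,
                feature_name=str(cell("feature_name") or "").strip(),
                disease=str(cell("disease") or "").strip(),
                category=canonical_category(cell("category"), warn=False),
                source=str(cell("source") or "").strip(),
                ground_truth=ground_truth,
                **numeric,
            )
            if not rec.feature_name:
                raise ValidationError(f"row {i}: empty feature name")
            rec.counts()  # surfaces invalid proportions / N early
            records.append(rec)
        except ValidationError as exc:
            if strict:
                raise ValidationError(f"{path} row {i}: {exc}") from exc
            rejects.append((i, str(exc)))

    if not records and strict:
        raise SchemaError(f"{path}: no valid rows")
    table = FeatureTable(
        records=records,
        source_file=str(path),
        read_at=datetime.now(timezone.utc).isoformat(),
        rejects=rejects,
    )
    log.info("read %d rows (%d rejected) from %s", len(records), len(rejects), path)
    return table


def _fmt(v) -> str:
    """Serialize a value: floats at 6 significant digits, None/NaN empty."""
    if v is None:
        return ""
    if isinstance(v, float):
        if np.isnan(v):
            return ""
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return f"{v:.6g}"
    return str(v)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table back to CSV (input-style schema)."""
    path = Path(path)
    cols = list(META_FIELDS) + list(PERF_FIELDS) + list(COUNT_FIELDS)
    has_gt = any(rec.ground_truth for rec in table)
    if has_gt:
        cols += ["er_fraction_true", "planted"]
    rows = []
    for rec in table:
        row = {f: _fmt(getattr(rec, f)) for f in cols if f not in ("er_fraction_true", "planted")}
        if has_gt:
            gt = rec.ground_truth or {}
            row["er_fraction_true"] = _fmt(gt.get("er_fraction"))
            row["planted"] = gt.get("planted", "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    log.info("wrote %d feature rows to %s", len(table), path)


def write_results(table: FeatureTable, results: pd.DataFrame, path: str | Path) -> None:
    """Write a computed results table to CSV.

    ``results`` must be aligned to ``table`` by feature_id (same ids,
    same order).  Columns are emitted in the fixed :data:`RESULT_COLUMNS`
    order; floats use 6 significant digits; row order is input order.
    """
    path = Path(path)
    ids_table = [rec.feature_id for rec in table]
    ids_results = [str(v) for v in results["feature_id"]]
    if ids_table != ids_results:
        raise ValidationError("results are not aligned to the table by feature_id")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results table is missing columns: {missing}")
    out = results.loc[:, list(RESULT_COLUMNS)].copy()
    for col in out.columns:
        out[col] = [
            _fmt(float(v)) if isinstance(v, (float, np.floating)) else _fmt(v)
            for v in out[col]
        ]
    out.to_csv(path, index=False)
    log.info("wrote %d result rows to %s", len(out), path)
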