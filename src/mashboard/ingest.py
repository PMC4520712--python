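"""Ingest per-county marginal CSV datasets.

A *marginal dataset* describes each US county (keyed by its 5-digit FIPS
code) through per-variable marginals: category counts for qualitative
variables (e.g. gender) and a single mean value for quantitative variables
(e.g. income per capita).  This module reads such tables from CSV, applies
automatic quality control with full accounting, and serializes the cleaned
result to a key-value JSON dialect together with variable metadata.

The QC policy is a closed list.  Auto-fixable defects: surrounding
whitespace, thousands separators inside numbers, and short FIPS codes
(left-padded with zeros to width 5).  Anything else — non-numeric or
negative counts, FIPS codes longer than 5 digits or non-numeric — drops the
whole row.  Nothing is ever repaired silently: each touched row increments
either ``n_auto_fixed`` or ``n_dropped`` in the :class:`QCReport`.

Rows whose FIPS ends in ``000`` are state-level records (the standard
county code for a state total) and are routed to the table's
``state_fallbacks`` rather than its county records.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import CollisionError, IngestError, SchemaError

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"

#: Tokens treated as a missing value (case-insensitive, after stripping).
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan"})


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one variable: name, source dataset, and data type."""

    name: str
    source: str
    kind: str
    categories: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (QUALITATIVE, QUANTITATIVE):
            raise IngestError(f"unknown variable kind {self.kind!r}")
        if self.kind == QUALITATIVE:
            if not self.categories:
                raise IngestError(f"qualitative variable {self.name!r} needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise IngestError(f"duplicate categories for {self.name!r}")
        elif self.categories is not None:
            raise IngestError(f"quantitative variable {self.name!r} must not list categories")

    def to_dict(self) -> dict:
        d = {"name": self.name, "source": self.source, "kind": self.kind}
        if self.kind == QUALITATIVE:
            d["categories"] = list(self.categories)
        else:
            d["units"] = self.units
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableMeta":
        return cls(
            name=d["name"],
            source=d["source"],
            kind=d["kind"],
            categories=tuple(d["categories"]) if d.get("categories") else None,
            units=d.get("units", ""),
        )


@dataclass
class MarginalTable:
    """Per-county marginals for one dataset.

    ``records`` maps a 5-character zero-padded FIPS string to a mapping
    from variable name to either a ``{category: count}`` dict (qualitative)
    or a plain number (quantitative mean).  ``state_fallbacks`` holds the
    same structure keyed by the 2-character state FIPS prefix, used when a
    county lacks a value.
    """

    dataset_label: str
    records: dict[str, dict] = field(default_factory=dict)
    state_fallbacks: dict[str, dict] = field(default_factory=dict)

    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.records.values():
            for var in row:
                seen.setdefault(var)
        return list(seen)

    def column(self, var: str) -> dict[str, object]:
        """All county values for one variable, keyed by FIPS."""
        return {geo: row[var] for geo, row in self.records.items() if var in row}


@dataclass
class QCReport:
    """Accounting of automatic fixes and drops for one validation run."""

    dataset_label: str
    n_input_rows: int
    n_auto_fixed: int
    n_dropped: int

    @property
    def error_rate(self) -> float:
        if self.n_input_rows == 0:
            return 0.0
        return (self.n_auto_fixed + self.n_dropped) / self.n_input_rows

    def to_dict(self) -> dict:
        return {
            "dataset_label": self.dataset_label,
            "n_input_rows": self.n_input_rows,
            "n_auto_fixed": self.n_auto_fixed,
            "n_dropped": self.n_dropped,
            "error_rate": self.error_rate,
        }


@dataclass
class SummaryMeta:
    """Cross-dataset catalogue: every dataset with its variable metadata."""

    datasets: list[tuple[str, list[VariableMeta]]]

    def all_metas(self) -> list[VariableMeta]:
        return [m for _, metas in self.datasets for m in metas]

    def meta_of(self, name: str) -> VariableMeta:
        for m in self.all_metas():
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.all_metas())

    def to_json(self) -> str:
        obj = {
            "datasets": [
                {"dataset": label, "variables": [m.to_dict() for m in metas]}
                for label, metas in self.datasets
            ]
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SummaryMeta":
        obj = json.loads(text)
        return cls(
            datasets=[
                (d["dataset"], [VariableMeta.from_dict(v) for v in d["variables"]])
                for d in obj["datasets"]
            ]
        )


# ---------------------------------------------------------------------------
# Column-role schema


@dataclass(frozen=True)
class VariableSchema:
    """How one variable is laid out in the CSV.

    Quantitative variables map to a single ``column``; qualitative variables
    map each category label to its count column via ``category_columns``.
    """

    name: str
    kind: str
    column: str | None = None
    category_columns: dict[str, str] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind == QUANTITATIVE and not self.column:
            raise SchemaError(f"quantitative variable {self.name!r} needs a column")
        if self.kind == QUALITATIVE and not self.category_columns:
            raise SchemaError(f"qualitative variable {self.name!r} needs category columns")

    def meta(self, source: str) -> VariableMeta:
        if self.kind == QUALITATIVE:
            return VariableMeta(self.name, source, self.kind, tuple(self.category_columns))
        return VariableMeta(self.name, source, self.kind, units=self.units)


@dataclass(frozen=True)
class TableSchema:
    dataset_label: str
    geo_column: str
    variables: tuple[VariableSchema, ...]

    @classmethod
    def from_dict(cls, d: dict) -> "TableSchema":
        variables = []
        for v in d["variables"]:
            variables.append(
                VariableSchema(
                    name=v["name"],
                    kind=v["kind"],
                    column=v.get("column"),
                    category_columns=v.get("categories"),
                    units=v.get("units", ""),
                )
            )
        return cls(d["dataset"], d["geo_column"], tuple(variables))

    @classmethod
    def from_json(cls, text: str) -> "TableSchema":
        return cls.from_dict(json.loads(text))

    def metas(self) -> list[VariableMeta]:
        return [v.meta(self.dataset_label) for v in self.variables]


# ---------------------------------------------------------------------------
# Operations


def read_marginal_csv(path, schema: TableSchema) -> MarginalTable:
    """Transcribe a marginal CSV into a raw :class:`MarginalTable`.

    Cell values are kept verbatim as strings; all repair and accounting is
    deferred to :func:`validate_records`.  If a geo id occurs twice the last
    row wins.  A missing geo column, a missing declared variable column, or
    a file without data rows is fatal.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=False)
    except pd.errors.EmptyDataError:
        raise IngestError(f"empty CSV file: {path}") from None
    if schema.geo_column not in df.columns:
        raise SchemaError(
            f"geo column {schema.geo_column!r} not in CSV header {list(df.columns)}"
        )
    for v in schema.variables:
        needed = [v.column] if v.kind == QUANTITATIVE else list(v.category_columns.values())
        for col in needed:
            if col not in df.columns:
                raise SchemaError(f"column {col!r} for variable {v.name!r} not in CSV header")
    if len(df) == 0:
        raise IngestError(f"CSV has a header but no data rows: {path}")

    records: dict[str, dict] = {}
    for _, row in df.iterrows():
        geo = row[schema.geo_column]
        rec: dict[str, object] = {}
        for v in schema.variables:
            if v.kind == QUANTITATIVE:
                rec[v.name] = row[v.column]
            else:
                rec[v.name] = {cat: row[col] for cat, col in v.category_columns.items()}
        records[geo] = rec
    return MarginalTable(schema.dataset_label, records)


_THOUSANDS = re.compile(r",")


def _parse_number(raw) -> tuple[float | None, bool, str]:
    """Parse one cell → (value, was_fixed, status in {ok, missing, bad})."""
    if raw is None:
        return None, False, "missing"
    if isinstance(raw, (int, float)):
        if isinstance(raw, float) and not math.isfinite(raw):
            return None, False, "bad"
        return raw, False, "ok"
    s = str(raw)
    t = s.strip()
    fixed = t != s
    if t.lower() in MISSING_TOKENS:
        return None, False, "missing"
    if "," in t:
        t = _THOUSANDS.sub("", t)
        fixed = True
    try:
        v = float(t)
    except ValueError:
        return None, False, "bad"
    if not math.isfinite(v):
        return None, False, "bad"
    return v, fixed, "ok"


def _parse_count(raw) -> tuple[int | None, bool, str]:
    v, fixed, status = _parse_number(raw)
    if status != "ok":
        return None, fixed, status
    if v < 0 or v != int(v):
        return None, fixed, "bad"
    return int(v), fixed, "ok"


def validate_records(table: MarginalTable) -> tuple[MarginalTable, QCReport]:
    """Repair or drop defective rows, returning a clean table and its QC report.

    Idempotent: validating an already-clean table returns an identical table
    and a zero-error report.  Never raises on data defects — every row is
    either kept (possibly auto-fixed) or dropped and counted.
    """
    records: dict[str, dict] = {}
    fallbacks: dict[str, dict] = {p: dict(v) for p, v in table.state_fallbacks.items()}
    n_input = len(table.records)
    n_fixed = 0
    n_dropped = 0

    for raw_geo, row in table.records.items():
        fixed = False
        geo = str(raw_geo)
        stripped = geo.strip()
        if stripped != geo:
            fixed = True
        geo = stripped
        if not geo.isdigit() or len(geo) > 5:
            n_dropped += 1
            continue
        if len(geo) < 5:
            geo = geo.zfill(5)
            fixed = True

        clean: dict[str, object] = {}
        bad = False
        for var, val in row.items():
            if isinstance(val, dict):
                counts: dict[str, int] = {}
                n_missing = 0
                for cat, cell in val.items():
                    c, f, status = _parse_count(cell)
                    if status == "bad":
                        bad = True
                        break
                    if status == "missing":
                        n_missing += 1
                        counts[cat] = 0
                    else:
                        counts[cat] = c
                        fixed = fixed or f
                if bad:
                    break
                if n_missing < len(val):  # at least one category present
                    clean[var] = counts
            else:
                v, f, status = _parse_number(val)
                if status == "bad":
                    bad = True
                    break
                if status == "ok":
                    clean[var] = v
                    fixed = fixed or f
        if bad:
            n_dropped += 1
            continue
        if fixed:
            n_fixed += 1
        if geo.endswith("000"):
            fallbacks.setdefault(geo[:2], {}).update(clean)
        else:
            records[geo] = clean

    report = QCReport(table.dataset_label, n_input, n_fixed, n_dropped)
    return MarginalTable(table.dataset_label, records, fallbacks), report


def dumps_keyvalue(table: MarginalTable, metas: list[VariableMeta]) -> str:
    """Serialize a clean table + metadata to the key-value JSON dialect.

    Layout: ``{"dataset": ..., "meta": [...], "records": {"<fips>":
    {"<var>": counts-or-mean}}, "state_fallbacks": {...}}`` with counts as
    integers and means as decimals.  Round-trips exactly through
    :func:`loads_keyvalue`.
    """
    by_name = {m.name: m for m in metas}
    for geo, row in table.records.items():
        for var in row:
            if var not in by_name:
                raise IngestError(f"variable {var!r} (county {geo}) has no metadata")
    obj = {
        "dataset": table.dataset_label,
        "meta": [m.to_dict() for m in metas],
        "records": table.records,
        "state_fallbacks": table.state_fallbacks,
    }
    return json.dumps(obj, indent=1)


def loads_keyvalue(text: str) -> tuple[MarginalTable, list[VariableMeta]]:
    obj = json.loads(text)
    metas = [VariableMeta.from_dict(d) for d in obj["meta"]]
    return (
        MarginalTable(obj["dataset"], obj["records"], obj.get("state_fallbacks", {})),
        metas,
    )


def write_keyvalue_json(table: MarginalTable, metas: list[VariableMeta], path) -> str:
    text = dumps_keyvalue(table, metas)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return text


def read_keyvalue_json(path) -> tuple[MarginalTable, list[VariableMeta]]:
    with open(path, encoding="utf-8") as fh:
        return loads_keyvalue(fh.read())


def build_summary(datasets: list[tuple[MarginalTable, list[VariableMeta]]]) -> SummaryMeta:
    """Combine per-dataset metadata into one catalogue.

    Variable names must be globally unique; a collision across datasets is
    an ingest-time error, not something resolved by renaming.
    """
    if not datasets:
        raise IngestError("build_summary needs at least one dataset")
    seen: dict[str, str] = {}
    out: list[tuple[str, list[VariableMeta]]] = []
    for table, metas in datasets:
        for m in metas:
            if m.name in seen:
                raise CollisionError(
                    f"variable {m.name!r} defined by both {seen[m.name]!r} "
                    f"and {table.dataset_label!r}"
                )
            seen[m.name] = table.dataset_label
        out.append((table.dataset_label, list(metas)))
    return SummaryMeta(out)
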