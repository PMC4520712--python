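"""Machine-facing query grammar over a fused pool, plus filtered export.

The grammar mirrors a REST query string: ``var[min]=v`` / ``var[max]=v``
set inclusive bounds on a quantitative variable, repeated ``var=label``
pairs union into a category set on a qualitative variable (disjunction
within a variable, conjunction across variables), and each ``reqVar=name``
names a variable to return.  For example::

    income_per_capita[min]=60000&race=White&race=Black&reqVar=avg_charge

requests ``avg_charge`` for samples with income at least 60,000 whose race
is White or Black.  Execution routes through the same filter engine the
interactive views use, so API results and GUI-style export agree exactly:
only records passing every active filter appear, and only the requested or
displayed variables are represented.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from urllib.parse import parse_qsl, quote_plus

import pandas as pd

from .errors import QueryError
from .filter_engine import CategorySet, FilterEngine, FilterState, Interval
from .ingest import QUALITATIVE, QUANTITATIVE, MarginalTable, SummaryMeta
from .fusion import SamplePool

REQ_VAR = "reqVar"
_BRACKET = re.compile(r"^(?P<var>.+)\[(?P<side>min|max)\]$")


@dataclass(frozen=True)
class Bounds:
    """Optional inclusive lower/upper bound on a quantitative variable."""

    min: float | None = None
    max: float | None = None

    def to_interval(self) -> Interval:
        lo = -float("inf") if self.min is None else self.min
        hi = float("inf") if self.max is None else self.max
        return Interval(lo, hi)


@dataclass
class QuerySpec:
    """Parsed form of a query string: filters plus requested variables."""

    filters: dict[str, object] = field(default_factory=dict)
    requested_vars: list[str] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, QuerySpec)
            and self.filters == other.filters
            and self.requested_vars == other.requested_vars
        )

    def to_filter_state(self) -> FilterState:
        preds = {}
        for var, f in self.filters.items():
            preds[var] = f.to_interval() if isinstance(f, Bounds) else f
        return FilterState(preds)


def parse_query(query_string: str, summary: SummaryMeta) -> QuerySpec:
    """Parse and validate a query string against the variable catalogue."""
    if not query_string:
        raise QueryError("empty query string")
    pairs = parse_qsl(query_string, keep_blank_values=True)
    if not pairs:
        raise QueryError(f"no key=value pairs in query {query_string!r}")
    spec = QuerySpec()
    for key, value in pairs:
        if key == REQ_VAR:
            if value not in summary:
                raise QueryError(f"unknown requested variable {value!r}")
            spec.requested_vars.append(value)
            continue
        m = _BRACKET.match(key)
        if m:
            var, side = m.group("var"), m.group("side")
            if var not in summary:
                raise QueryError(f"unknown variable {var!r}")
            if summary.meta_of(var).kind != QUANTITATIVE:
                raise QueryError(f"[{side}] bound on qualitative variable {var!r}")
            try:
                bound = float(value)
            except ValueError:
                raise QueryError(f"non-numeric bound {value!r} for {var!r}") from None
            prior = spec.filters.get(var, Bounds())
            if not isinstance(prior, Bounds):
                raise QueryError(f"mixed bound/category filters on {var!r}")
            spec.filters[var] = (
                Bounds(min=bound, max=prior.max)
                if side == "min"
                else Bounds(min=prior.min, max=bound)
            )
        else:
            if key not in summary:
                raise QueryError(f"unknown variable {key!r}")
            if summary.meta_of(key).kind != QUALITATIVE:
                raise QueryError(
                    f"category filter on quantitative variable {key!r}; use [min]/[max]"
                )
            prior = spec.filters.get(key)
            labels = {value} if prior is None else set(prior.labels) | {value}
            spec.filters[key] = CategorySet(labels)
    if not spec.requested_vars:
        raise QueryError("query names no requested variable (reqVar=...)")
    return spec


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def render_query(spec: QuerySpec) -> str:
    """Render a QuerySpec back to a query string (parse round-trips it)."""
    parts: list[str] = []
    for var, f in spec.filters.items():
        if isinstance(f, Bounds):
            if f.min is not None:
                parts.append(f"{quote_plus(var)}[min]={_fmt_num(f.min)}")
            if f.max is not None:
                parts.append(f"{quote_plus(var)}[max]={_fmt_num(f.max)}")
        else:
            for label in sorted(f.labels):
                parts.append(f"{quote_plus(var)}={quote_plus(label)}")
    for var in spec.requested_vars:
        parts.append(f"{REQ_VAR}={quote_plus(var)}")
    return "&".join(parts)


def execute_query(pool: SamplePool, spec: QuerySpec) -> pd.DataFrame:
    """Run a parsed query against the pool via the filter engine.

    Returns the requested variables for exactly the samples passing every
    filter, indexed by sample id — identical to what the interactive
    filter path selects under the same state.
    """
    for var in list(spec.filters) + spec.requested_vars:
        if var not in pool.integrated:
            raise QueryError(f"variable {var!r} is not integrated in the pool")
    engine = FilterEngine(pool, max_views=max(30, len(spec.filters)))
    for var in spec.filters:
        engine.add_dimension(var)
    ids = engine.current_selection(spec.to_filter_state())
    return pool.data.loc[ids, spec.requested_vars].copy()


def export_csv(pool: SamplePool, state: FilterState, displayed_vars: list[str]) -> str:
    """Export-tile semantics: filtered rows, displayed columns, plus weight.

    One row per sample passing all currently applied filters; columns are
    the displayed variables in the given order plus the sample weight.
    Deterministic: identical state yields identical bytes.
    """
    for var in displayed_vars:
        if var not in pool.integrated:
            raise QueryError(f"variable {var!r} is not integrated in the pool")
    engine = FilterEngine(pool, max_views=max(30, len(state)))
    for var in state:
        engine.add_dimension(var)
    ids = engine.current_selection(state)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(list(displayed_vars) + ["weight"])
    w = pool.scale_denominator
    sub = pool.data.loc[ids, displayed_vars]
    for _, row in sub.iterrows():
        writer.writerow([row[v] for v in displayed_vars] + [w])
    return buf.getvalue()


def raw_variable(tables, var: str) -> dict[str, object]:
    """Unfiltered per-county values for one variable, keyed by FIPS.

    Mirrors the two raw REST endpoints: quantitative variables return
    county means, qualitative ones their category-count maps.  No filters
    apply.  ``tables`` is one MarginalTable or an iterable of them.
    """
    if isinstance(tables, MarginalTable):
        tables = [tables]
    for table in tables:
        col = table.column(var)
        if col:
            return col
    raise QueryError(f"unknown variable {var!r}")
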