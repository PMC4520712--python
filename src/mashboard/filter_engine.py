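"""Crossfilter-style coordinated filtering over a sample pool.

Every view of the pool shares one :class:`FilterState`.  A predicate set on
one dimension restricts what every *other* dimension sees, while a
dimension's own group aggregation excludes its own predicate — the brushed
chart keeps its full axis, everything else narrows.  Correctness is defined
by a naive full-scan oracle; the per-dimension sorted/categorical indexes
exist only so repeated re-filtering does not rescan the pool.

Predicates: closed numeric intervals ``[lo, hi]`` on quantitative
dimensions; non-empty category sets (disjunction within the set) on
qualitative dimensions.  Predicates on different dimensions combine by
conjunction; setting a predicate on a dimension replaces any prior one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FilterError, LimitError
from .ingest import QUALITATIVE, QUANTITATIVE
from .fusion import SamplePool

COUNT = "count"


@dataclass(frozen=True)
class Interval:
    """Closed numeric interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise FilterError(f"interval requires lo <= hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class CategorySet:
    """Non-empty set of category labels; membership in any label passes."""

    labels: frozenset

    def __init__(self, labels):
        object.__setattr__(self, "labels", frozenset(labels))
        if not self.labels:
            raise FilterError("CategorySet must be non-empty")


class FilterState(Mapping):
    """Immutable map dimension-variable -> predicate.

    ``set``/``clear`` return new states, so any sequence of operations is
    equivalent to building the final state from scratch.
    """

    def __init__(self, predicates: dict | None = None):
        self._predicates = dict(predicates or {})

    def set(self, var: str, predicate) -> "FilterState":
        d = dict(self._predicates)
        d[var] = predicate
        return FilterState(d)

    def clear(self, var: str) -> "FilterState":
        d = dict(self._predicates)
        d.pop(var, None)
        return FilterState(d)

    def __getitem__(self, var):
        return self._predicates[var]

    def __iter__(self):
        return iter(self._predicates)

    def __len__(self):
        return len(self._predicates)

    def __repr__(self):
        return f"FilterState({self._predicates!r})"

    def to_json_dict(self) -> dict:
        out = {}
        for var, p in self._predicates.items():
            if isinstance(p, Interval):
                out[var] = {"interval": [p.lo, p.hi]}
            else:
                out[var] = {"categories": sorted(p.labels)}
        return out

    @classmethod
    def from_json_dict(cls, d: dict) -> "FilterState":
        preds = {}
        for var, spec in d.items():
            if "interval" in spec:
                preds[var] = Interval(*spec["interval"])
            else:
                preds[var] = CategorySet(spec["categories"])
        return cls(preds)


class Dimension:
    """Index over one integrated variable of the pool."""

    def __init__(self, pool: SamplePool, var: str):
        self.var = var
        self.kind = pool.kind_of(var)
        vals = pool.values(var)
        if self.kind == QUANTITATIVE:
            self.values = vals.astype(float)
            self.order = np.argsort(self.values, kind="stable")  # NaN sorts last
            self.sorted_values = self.values[self.order]
            self.n_valid = int(np.count_nonzero(~np.isnan(self.values)))
        else:
            codes, cats = pd.factorize(pd.Series(vals, dtype=object), use_na_sentinel=True)
            self.codes = codes
            self.categories = [c for c in cats]
            self._code_of = {c: i for i, c in enumerate(self.categories)}
            self.n = len(vals)

    def mask(self, predicate) -> np.ndarray:
        """Boolean membership mask for one predicate (missing values fail)."""
        if self.kind == QUANTITATIVE:
            if not isinstance(predicate, Interval):
                raise FilterError(
                    f"dimension {self.var!r} is quantitative; use an Interval"
                )
            a = np.searchsorted(self.sorted_values[: self.n_valid], predicate.lo, "left")
            b = np.searchsorted(self.sorted_values[: self.n_valid], predicate.hi, "right")
            m = np.zeros(len(self.values), dtype=bool)
            m[self.order[a:b]] = True
            return m
        if not isinstance(predicate, CategorySet):
            raise FilterError(f"dimension {self.var!r} is qualitative; use a CategorySet")
        wanted = [self._code_of[l] for l in predicate.labels if l in self._code_of]
        if not wanted:
            return np.zeros(self.n, dtype=bool)
        return np.isin(self.codes, wanted)


class FilterEngine:
    """Registry of dimensions over one pool, evaluating shared filter states."""

    def __init__(self, pool: SamplePool, max_views: int = 30, max_vars_per_view: int = 6):
        self.pool = pool
        self.max_views = max_views
        self.max_vars_per_view = max_vars_per_view
        self.dimensions: dict[str, Dimension] = {}

    def add_dimension(self, var: str) -> Dimension:
        """Register a dimension; never changes the current selection."""
        if var in self.dimensions:
            return self.dimensions[var]
        if len(self.dimensions) + 1 > self.max_views:
            raise LimitError(
                f"cannot add dimension {var!r}: view limit of {self.max_views} reached"
            )
        if var not in self.pool.integrated:
            raise FilterError(f"variable {var!r} is not integrated in the pool")
        dim = Dimension(self.pool, var)
        self.dimensions[var] = dim
        return dim

    def validate_view(self, variables: list[str]) -> None:
        """Enforce the per-view variable-count limit (1..max_vars_per_view)."""
        if not 1 <= len(variables) <= self.max_vars_per_view:
            raise LimitError(
                f"a view takes between 1 and {self.max_vars_per_view} variables, "
                f"got {len(variables)}"
            )

    def _dim(self, var: str) -> Dimension:
        if var not in self.dimensions:
            raise FilterError(f"no dimension registered for {var!r}")
        return self.dimensions[var]

    def selection_mask(self, state: FilterState, exclude: str | None = None) -> np.ndarray:
        """AND of all predicate masks, optionally excluding one dimension's own."""
        m = np.ones(self.pool.size, dtype=bool)
        for var in state:
            if var == exclude:
                continue
            m &= self._dim(var).mask(state[var])
        return m

    def current_selection(self, state: FilterState) -> np.ndarray:
        """Sample ids satisfying the conjunction of all active predicates."""
        return self.pool.sample_ids[self.selection_mask(state)]

    def group_aggregate(
        self, dim: Dimension, state: FilterState, stat=COUNT, bins=None
    ) -> dict:
        """Per-category (or per-bin) aggregate under all *other* filters.

        ``stat`` is ``"count"`` or a tuple ``("sum", var)`` / ``("mean",
        var)`` over a quantitative variable.  ``bins``, for quantitative
        dimensions, is a sequence of edges defining half-open bins with the
        last bin closed at the top; without ``bins`` each distinct value is
        its own group.
        """
        if stat == COUNT:
            target = None
        else:
            op, var = stat
            if op not in ("sum", "mean"):
                raise FilterError(f"unknown statistic {op!r}")
            if self.pool.kind_of(var) != QUANTITATIVE:
                raise FilterError(f"cannot {op} qualitative variable {var!r}")
            target = self.pool.values(var).astype(float)
        external = self.selection_mask(state, exclude=dim.var)

        def agg(member: np.ndarray):
            both = member & external
            n = int(both.sum())
            if stat == COUNT:
                return n
            if n == 0:
                return float("nan")
            s = float(target[both].sum())
            return s if stat[0] == "sum" else s / n

        out: dict = {}
        if dim.kind == QUALITATIVE:
            for code, cat in enumerate(dim.categories):
                out[cat] = agg(dim.codes == code)
            return out
        if bins is None:
            for v in np.unique(dim.values[~np.isnan(dim.values)]):
                out[float(v)] = agg(dim.values == v)
            return out
        edges = np.asarray(bins, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise FilterError("bins must be a strictly increasing sequence of >= 2 edges")
        idx = np.searchsorted(edges, dim.values, side="right") - 1
        idx[dim.values == edges[-1]] = len(edges) - 2  # top bin closed
        for i in range(len(edges) - 1):
            out[(float(edges[i]), float(edges[i + 1]))] = agg(idx == i)
        return out


# -- spec-style functional facade -------------------------------------------


def add_dimension(engine: FilterEngine, var: str) -> Dimension:
    return engine.add_dimension(var)


def set_filter(state: FilterState, dim: Dimension, predicate) -> FilterState:
    """Replace the predicate on ``dim`` (type-checked against its kind)."""
    if dim.kind == QUANTITATIVE and not isinstance(predicate, Interval):
        raise FilterError(f"dimension {dim.var!r} takes an Interval")
    if dim.kind == QUALITATIVE and not isinstance(predicate, CategorySet):
        raise FilterError(f"dimension {dim.var!r} takes a CategorySet")
    return state.set(dim.var, predicate)


def clear_filter(state: FilterState, dim: Dimension) -> FilterState:
    return state.clear(dim.var)


def current_selection(engine: FilterEngine, state: FilterState) -> np.ndarray:
    return engine.current_selection(state)
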