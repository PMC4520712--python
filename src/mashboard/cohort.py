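"""Location-free ("free-anchored") dataset integration via cohort binning.

Datasets without a geographic key are joined on a shared *anchor* variable
(e.g. a ``cerebellum_Volume`` column present in every file).  The user
names the anchor, a range ``[lo, hi]`` and a cohort count ``n``; rows fall
into ``n`` equal-width bins of the anchor, and the cohort index then plays
the role the county FIPS code plays in the location-anchored mode, so the
merged records feed the same filter engine unchanged.

Variable kinds are inferred from the entries themselves — a column is
quantitative iff every non-missing entry parses as a finite number — so no
user-supplied metadata is needed.  Bins are half-open ``[lo+i*w, lo+(i+1)*w)``
with the final bin closed at ``hi``; anchor values outside ``[lo, hi]`` (or
missing) are dropped and counted, never silently lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortError
from .ingest import MISSING_TOKENS, QUALITATIVE, QUANTITATIVE, VariableMeta
from .fusion import SamplePool

COHORT_VAR = "cohort"


@dataclass(frozen=True)
class CohortSpec:
    """Anchor variable plus binning range and cohort count."""

    anchor_var: str
    lo: float
    hi: float
    n_cohorts: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise CohortError(f"cohort range requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.n_cohorts < 1:
            raise CohortError("n_cohorts must be >= 1")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_cohorts

    def edge(self, i: int) -> float:
        # each edge computed directly from the range, never by repeated addition
        return self.lo + i * (self.hi - self.lo) / self.n_cohorts

    def cohort_of(self, v: float) -> int | None:
        """Cohort index for one anchor value, or None if out of range/missing."""
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if v < self.lo or v > self.hi:
            return None
        i = int(math.floor((v - self.lo) / self.width))
        return min(i, self.n_cohorts - 1)  # v == hi lands in the closed top bin


@dataclass
class AnchoredDataset:
    """A user CSV with inferred column kinds and (after assignment) cohorts."""

    label: str
    rows: pd.DataFrame
    inferred: dict[str, str]
    cohort_of: np.ndarray | None = None
    n_dropped: int = 0
    spec: CohortSpec | None = field(default=None)


def _is_missing(raw: str) -> bool:
    return raw.strip().lower() in MISSING_TOKENS


def infer_variable_kind(values) -> str:
    """Quantitative iff every non-missing entry parses as a finite number."""
    non_missing = [str(v) for v in values if not _is_missing(str(v))]
    if not non_missing:
        raise CohortError("cannot infer the kind of an all-missing column")
    for v in non_missing:
        try:
            x = float(v.strip())
        except ValueError:
            return QUALITATIVE
        if not math.isfinite(x):
            return QUALITATIVE
    return QUANTITATIVE


def read_anchored_csv(source, label: str) -> AnchoredDataset:
    """Read a user CSV (path or buffer), inferring each column's kind.

    Quantitative columns become floats (missing -> NaN); qualitative
    columns keep their string labels (missing -> None).
    """
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    if len(raw.columns) == 0:
        raise CohortError(f"dataset {label!r} has no columns")
    inferred: dict[str, str] = {}
    out: dict[str, object] = {}
    for col in raw.columns:
        kind = infer_variable_kind(raw[col]) if len(raw) else QUANTITATIVE
        inferred[col] = kind
        if kind == QUANTITATIVE:
            out[col] = pd.to_numeric(
                raw[col].map(lambda s: np.nan if _is_missing(s) else s.strip()),
                errors="coerce",
            ).astype(float)
        else:
            out[col] = raw[col].map(lambda s: None if _is_missing(s) else s.strip())
    return AnchoredDataset(label, pd.DataFrame(out, index=raw.index), inferred)


def assign_cohorts(dataset: AnchoredDataset, spec: CohortSpec) -> AnchoredDataset:
    """Bin every row by its anchor value; out-of-range rows are dropped.

    Returns a new dataset containing only retained rows, each mapped to
    exactly one cohort index in ``[0, n_cohorts)``, with the drop count
    recorded.
    """
    if spec.anchor_var not in dataset.rows.columns:
        raise CohortError(f"dataset {dataset.label!r} has no column {spec.anchor_var!r}")
    if dataset.inferred.get(spec.anchor_var) != QUANTITATIVE:
        raise CohortError(
            f"anchor {spec.anchor_var!r} in dataset {dataset.label!r} is qualitative"
        )
    anchors = dataset.rows[spec.anchor_var].to_numpy(dtype=float)
    idx = np.array(
        [(-1 if (c := spec.cohort_of(v)) is None else c) for v in anchors], dtype=int
    )
    keep = idx >= 0
    kept = dataset.rows.loc[keep].reset_index(drop=True)
    return AnchoredDataset(
        label=dataset.label,
        rows=kept,
        inferred=dict(dataset.inferred),
        cohort_of=idx[keep],
        n_dropped=int((~keep).sum()),
        spec=spec,
    )


def merge_on_cohort(datasets: list[AnchoredDataset], spec: CohortSpec) -> SamplePool:
    """Concatenate cohort-assigned datasets into one filterable pool.

    Columns are prefixed ``<label>.<column>`` to avoid collisions, except
    the shared anchor which keeps its name.  The cohort index (also exposed
    as the quantitative variable ``cohort``) plays the role of the county
    id, so the result feeds :class:`~mashboard.filter_engine.FilterEngine`
    directly.  Each record carries weight 1: these are real user rows, not
    scaled synthetic samples.
    """
    if not datasets:
        raise CohortError("merge_on_cohort needs at least one dataset")
    frames = []
    metas: dict[str, VariableMeta] = {}
    for ds in datasets:
        if ds.cohort_of is None or ds.spec is None:
            raise CohortError(f"dataset {ds.label!r} has not been cohort-assigned")
        if ds.spec != spec:
            raise CohortError(
                f"dataset {ds.label!r} was assigned under a different cohort spec"
            )
        renamed = {}
        for col in ds.rows.columns:
            name = col if col == spec.anchor_var else f"{ds.label}.{col}"
            renamed[col] = name
            if name not in metas:
                kind = ds.inferred[col]
                if kind == QUALITATIVE:
                    labels = sorted(
                        {v for v in ds.rows[col] if v is not None}
                    ) or ["<empty>"]
                    metas[name] = VariableMeta(name, ds.label, kind, tuple(labels))
                else:
                    metas[name] = VariableMeta(name, ds.label, kind)
        f = ds.rows.rename(columns=renamed).copy()
        f["geo_id"] = [str(int(c)).zfill(5) for c in ds.cohort_of]
        f[COHORT_VAR] = ds.cohort_of.astype(float)
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True, sort=False)
    metas[COHORT_VAR] = VariableMeta(COHORT_VAR, "cohort", QUANTITATIVE)
    # qualitative columns absent from a frame arrive as NaN; normalize to None
    for name, m in metas.items():
        if m.kind == QUALITATIVE:
            merged[name] = merged[name].where(pd.notna(merged[name]), None)
    return SamplePool(merged, scale_denominator=1, rng_seed=0, integrated=metas)
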