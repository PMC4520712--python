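"""Build the synthetic sample pool and integrate variables into it.

The fused archive is represented by *simulation* rather than by raw
microdata: each county contributes ``round_half_up(population / D)``
weighted samples, where ``D`` is the scale denominator (default 1,000, i.e.
a 1/1,000 population sample and every sample stands for 1,000 people).

Qualitative variables are assigned by simple random sampling from the
county's category distribution — a county with 3,000 males and 5,000
females yields 8 samples of which on average 3 are male and 5 female.
Quantitative variables are set to the county mean (state mean as fallback)
with no simulated deviation; within a county every sample carries the same
value.  Because no sample corresponds to a real individual and the smallest
representable unit is ``D`` persons, the pool reveals nothing about raw
records.

Seeding: the pool carries one seed; each variable integration draws from a
sub-stream derived from ``(seed, variable name, county)``, so integrating
variables lazily (as a dashboard requesting them on demand would) or
eagerly, in any order, yields attribute-identical pools.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import FusionError, IntegrationError
from .ingest import QUALITATIVE, QUANTITATIVE, MarginalTable, VariableMeta

ADD, SUBTRACT, MULTIPLY = "add", "subtract", "multiply"


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero-ward halves up."""
    return int(math.floor(x + 0.5))


def _var_stream(seed: int, var: str, geo: str) -> np.random.Generator:
    # crc32 keeps the sub-stream derivation stable across processes
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(var.encode("utf-8")), int(geo)])
    )


@dataclass(frozen=True)
class Sample:
    """One weighted synthetic sample: a county id plus assigned attributes."""

    sample_id: int
    geo_id: str
    weight: int
    attributes: dict


class SamplePool:
    """The fused synthetic population.

    Internally a pandas DataFrame indexed by sample id with a ``geo_id``
    column and one column per integrated variable; ``integrated`` maps each
    variable name to its :class:`VariableMeta`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scale_denominator: int,
        rng_seed: int,
        integrated: dict[str, VariableMeta] | None = None,
    ):
        if scale_denominator < 1:
            raise FusionError("scale_denominator must be >= 1")
        self.data = data
        self.scale_denominator = int(scale_denominator)
        self.rng_seed = int(rng_seed)
        self.integrated = dict(integrated or {})

    # -- basic views -------------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def counties(self) -> list[str]:
        return sorted(self.data["geo_id"].unique())

    def geo_ids(self) -> np.ndarray:
        return self.data["geo_id"].to_numpy()

    def values(self, var: str) -> np.ndarray:
        if var not in self.integrated:
            raise IntegrationError(f"variable {var!r} is not integrated in the pool")
        return self.data[var].to_numpy()

    def kind_of(self, var: str) -> str:
        return self.integrated[var].kind

    @property
    def samples(self) -> Iterator[Sample]:
        w = self.scale_denominator
        attr_cols = list(self.integrated)
        for sid, row in self.data.iterrows():
            yield Sample(int(sid), row["geo_id"], w, {c: row[c] for c in attr_cols})

    def total_weight(self) -> int:
        return self.size * self.scale_denominator

    def copy(self) -> "SamplePool":
        return SamplePool(
            self.data.copy(), self.scale_denominator, self.rng_seed, dict(self.integrated)
        )

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        cols = list(self.integrated)
        samples = []
        for sid, row in self.data.iterrows():
            rec = {"sample_id": int(sid), "geo_id": row["geo_id"]}
            for c in cols:
                v = row[c]
                rec[c] = None if (isinstance(v, float) and math.isnan(v)) else v
            samples.append(rec)
        obj = {
            "scale_denominator": self.scale_denominator,
            "rng_seed": self.rng_seed,
            "integrated": [self.integrated[c].to_dict() for c in cols],
            "samples": samples,
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SamplePool":
        obj = json.loads(text)
        metas = {d["name"]: VariableMeta.from_dict(d) for d in obj["integrated"]}
        df = pd.DataFrame(obj["samples"])
        if len(df) == 0:
            df = pd.DataFrame({"geo_id": pd.Series(dtype=str)})
        else:
            df = df.set_index("sample_id")
            df.index.name = None
        return cls(df, obj["scale_denominator"], obj["rng_seed"], metas)


# ---------------------------------------------------------------------------
# Operations


def build_pool(
    census: MarginalTable,
    population_var: str,
    scale_denominator: int = 1000,
    seed: int = 0,
) -> SamplePool:
    """Create the base pool from the mandatory census table.

    Every county gets ``round_half_up(population / scale_denominator)``
    samples with empty attributes.  A county without the population
    variable is fatal: the census is the base dataset the whole archive
    calibrates against.
    """
    geos: list[str] = []
    for geo in sorted(census.records):
        row = census.records[geo]
        if population_var not in row:
            raise FusionError(f"county {geo} lacks population variable {population_var!r}")
        pop = row[population_var]
        if isinstance(pop, dict):
            raise FusionError(f"population variable {population_var!r} must be quantitative")
        if pop < 0:
            raise FusionError(f"county {geo} has negative population {pop}")
        geos.extend([geo] * round_half_up(pop / scale_denominator))
    data = pd.DataFrame({"geo_id": pd.Series(geos, dtype=str)})
    return SamplePool(data, scale_denominator, seed)


def _state_fallback_counts(
    geo: str, counts: dict[str, dict], state_fallbacks: dict[str, dict] | None, var: str
) -> dict | None:
    prefix = geo[:2]
    if state_fallbacks and var in state_fallbacks.get(prefix, {}):
        return state_fallbacks[prefix][var]
    if f"{prefix}000" in counts:
        return counts[f"{prefix}000"]
    # aggregate the state's county-level counts
    agg: dict[str, int] = {}
    for g, c in counts.items():
        if g[:2] == prefix:
            for cat, n in c.items():
                agg[cat] = agg.get(cat, 0) + n
    return agg or None


def integrate_qualitative(
    pool: SamplePool,
    var: str,
    counts: dict[str, dict],
    meta: VariableMeta,
    seed: int | None = None,
    state_fallbacks: dict[str, dict] | None = None,
) -> SamplePool:
    """Assign a qualitative variable by simple random sampling per county.

    Each sample in county *c* independently draws category *k* with
    probability ``counts_c(k) / sum_j counts_c(j)``.  Counties missing from
    ``counts`` fall back to state-aggregated counts; all-zero counts are an
    error because no distribution exists.
    """
    if var in pool.integrated:
        raise IntegrationError(f"variable {var!r} already integrated")
    if meta.kind != QUALITATIVE:
        raise IntegrationError(f"{var!r} is not qualitative")
    if seed is None:
        seed = pool.rng_seed
    cats = list(meta.categories)
    col = np.empty(pool.size, dtype=object)
    geo_arr = pool.geo_ids()
    for geo in pool.counties():
        c = counts.get(geo)
        if c is None:
            c = _state_fallback_counts(geo, counts, state_fallbacks, var)
        if c is None:
            raise IntegrationError(f"no counts for {var!r} in county {geo} or its state")
        vec = np.array([c.get(cat, 0) for cat in cats], dtype=float)
        total = vec.sum()
        if total <= 0:
            raise IntegrationError(f"all-zero counts for {var!r} in county {geo}")
        idx = np.flatnonzero(geo_arr == geo)
        rng = _var_stream(seed, var, geo)
        col[idx] = rng.choice(cats, size=len(idx), p=vec / total)
    pool.data[var] = col
    pool.integrated[var] = meta
    return pool


def integrate_quantitative(
    pool: SamplePool,
    var: str,
    county_means: dict[str, float],
    state_means: dict[str, float] | None = None,
    meta: VariableMeta | None = None,
) -> SamplePool:
    """Assign a quantitative variable as the county (or state) mean.

    Deterministic constant propagation — no distribution or simulated
    deviation from the mean; within-county sample variance is exactly 0.
    ``state_means`` is keyed by the 2-character state prefix.
    """
    if meta is None:
        raise IntegrationError("meta is required")
    if var in pool.integrated:
        raise IntegrationError(f"variable {var!r} already integrated")
    if meta.kind != QUANTITATIVE:
        raise IntegrationError(f"{var!r} is not quantitative")
    state_means = state_means or {}
    col = np.full(pool.size, np.nan)
    geo_arr = pool.geo_ids()
    for geo in pool.counties():
        m = county_means.get(geo)
        if m is None:
            m = state_means.get(geo[:2])
        if m is None:
            raise IntegrationError(
                f"county {geo}: no county or state mean available for {var!r}"
            )
        col[geo_arr == geo] = float(m)
    pool.data[var] = col
    pool.integrated[var] = meta
    return pool


def integrate_from_table(
    pool: SamplePool,
    table: MarginalTable,
    var: str,
    meta: VariableMeta,
    seed: int | None = None,
) -> SamplePool:
    """Integrate ``var`` straight from a validated marginal table."""
    values = table.column(var)
    if meta.kind == QUALITATIVE:
        return integrate_qualitative(
            pool, var, values, meta, seed=seed, state_fallbacks=table.state_fallbacks
        )
    state_means = {
        prefix: row[var] for prefix, row in table.state_fallbacks.items() if var in row
    }
    return integrate_quantitative(pool, var, values, state_means, meta)


def derive_variable(
    pool: SamplePool, new_name: str, left: str, op: str, right: str
) -> SamplePool:
    """Register ``new_name = left <op> right`` computed per sample."""
    if new_name in pool.integrated:
        raise IntegrationError(f"variable name {new_name!r} already in use")
    for operand in (left, right):
        if operand not in pool.integrated:
            raise IntegrationError(f"operand {operand!r} is not integrated")
        if pool.integrated[operand].kind != QUANTITATIVE:
            raise IntegrationError(f"operand {operand!r} is not quantitative")
    lv = pool.data[left].to_numpy(dtype=float)
    rv = pool.data[right].to_numpy(dtype=float)
    if op == ADD:
        out = lv + rv
    elif op == SUBTRACT:
        out = lv - rv
    elif op == MULTIPLY:
        out = lv * rv
    else:
        raise IntegrationError(f"unknown operation {op!r} (use add/subtract/multiply)")
    pool.data[new_name] = out
    pool.integrated[new_name] = VariableMeta(new_name, "derived", QUANTITATIVE)
    return pool
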