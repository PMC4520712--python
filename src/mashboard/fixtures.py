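"""Deterministic toy-data generators.

Every module of the package is exercisable without downloading anything:
these generators produce small county-marginal tables shaped like the
census / labor / Medicare inputs the dashboard fuses, anchored CSV pairs
shaped like neuroimaging study exports (sharing a ``cerebellum_Volume``
column), and deliberately dirtied CSVs with known ground-truth defect
counts for exercising the QC pipeline.

Two named fixtures recur throughout the documentation and tests:

* ``worked_example`` — one county of population 8,000 with 3,000 males and
  5,000 females; at the default 1/1,000 scale it fuses to exactly 8
  samples of which on average 3 draw male and 5 female.
* ``cerebellum_pair`` — two location-free study files sharing the
  ``cerebellum_Volume`` anchor, made to be cohorted over [0, 300000] in
  300 bins.

All generators are byte-deterministic given their seed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

from .ingest import (
    QUALITATIVE,
    QUANTITATIVE,
    MarginalTable,
    TableSchema,
    VariableMeta,
    VariableSchema,
)

_STATE_PREFIXES = ("01", "06", "26", "36", "48")


@dataclass(frozen=True)
class QualitativeSpec:
    name: str
    categories: tuple[str, ...]
    concentration: float = 4.0  # Dirichlet prior over category proportions


@dataclass(frozen=True)
class QuantitativeSpec:
    name: str
    mean_range: tuple[float, float]
    units: str = ""


@dataclass(frozen=True)
class FixtureConfig:
    n_counties: int = 5
    population_range: tuple[int, int] = (2_000, 50_000)
    qualitative: tuple[QualitativeSpec, ...] = (
        QualitativeSpec("gender", ("male", "female")),
    )
    quantitative: tuple[QuantitativeSpec, ...] = (
        QuantitativeSpec("income_per_capita", (18_000.0, 65_000.0), "USD"),
    )
    seed: int = 0
    dataset_label: str = "toy_census"
    population_var: str = "population"


def _fips_sequence(n: int) -> list[str]:
    out = []
    for i in range(n):
        prefix = _STATE_PREFIXES[i % len(_STATE_PREFIXES)]
        county = 1 + 2 * (i // len(_STATE_PREFIXES))  # odd codes, like real FIPS
        out.append(prefix + str(county).zfill(3))
    return out


def make_county_fixture(config: FixtureConfig) -> tuple[MarginalTable, list[VariableMeta]]:
    """Generate a clean county-marginal table (passes QC with zero fixes)."""
    rng = np.random.default_rng(config.seed)
    records: dict[str, dict] = {}
    for geo in _fips_sequence(config.n_counties):
        lo, hi = config.population_range
        pop = int(rng.integers(lo, hi + 1))
        row: dict[str, object] = {config.population_var: pop}
        for q in config.qualitative:
            p = rng.dirichlet([q.concentration] * len(q.categories))
            counts = rng.multinomial(pop, p)
            row[q.name] = {cat: int(c) for cat, c in zip(q.categories, counts)}
        for q in config.quantitative:
            row[q.name] = round(float(rng.uniform(*q.mean_range)), 2)
        records[geo] = row
    metas = [VariableMeta(config.population_var, config.dataset_label, QUANTITATIVE, units="persons")]
    metas += [
        VariableMeta(q.name, config.dataset_label, QUALITATIVE, q.categories)
        for q in config.qualitative
    ]
    metas += [
        VariableMeta(q.name, config.dataset_label, QUANTITATIVE, units=q.units)
        for q in config.quantitative
    ]
    return MarginalTable(config.dataset_label, records), metas


def worked_example() -> tuple[MarginalTable, list[VariableMeta]]:
    """The canonical single-county example: pop 8,000; 3,000 male / 5,000 female."""
    table = MarginalTable(
        "worked_example",
        {"26161": {"population": 8000, "gender": {"male": 3000, "female": 5000}}},
    )
    metas = [
        VariableMeta("population", "worked_example", QUANTITATIVE, units="persons"),
        VariableMeta("gender", "worked_example", QUALITATIVE, ("male", "female")),
    ]
    return table, metas


def worked_example_schema() -> TableSchema:
    return TableSchema(
        "worked_example",
        "fips",
        (
            VariableSchema("population", QUANTITATIVE, column="pop"),
            VariableSchema(
                "gender", QUALITATIVE, category_columns={"male": "male", "female": "female"}
            ),
        ),
    )


def worked_example_csv() -> str:
    return "fips,pop,male,female\r\n26161,8000,3000,5000\r\n"


# ---------------------------------------------------------------------------
# Anchored (location-free) fixtures


def make_anchored_fixture(
    n_rows: int,
    anchor_name: str = "cerebellum_Volume",
    anchor_range: tuple[float, float] = (0.0, 300_000.0),
    extra_quantitative: tuple[str, ...] = ("orbitofrontal_Volume",),
    extra_qualitative: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> str:
    """CSV text for a location-free study file sharing an anchor column."""
    extra_qualitative = extra_qualitative or {"sex": ("M", "F")}
    rng = np.random.default_rng(seed)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    header = [anchor_name, *extra_quantitative, *extra_qualitative]
    writer.writerow(header)
    for _ in range(n_rows):
        row: list[object] = [round(float(rng.uniform(*anchor_range)), 1)]
        for _q in extra_quantitative:
            row.append(round(float(rng.normal(20_000.0, 4_000.0)), 1))
        for labels in extra_qualitative.values():
            row.append(labels[int(rng.integers(len(labels)))])
        writer.writerow(row)
    return buf.getvalue()


def cerebellum_pair(n_rows: int = 120, seed: int = 0) -> dict[str, str]:
    """Two study files joinable on ``cerebellum_Volume`` over [0, 300000].

    Emulates the shape of two neurodegeneration cohorts exported from
    different studies: same anchor column, otherwise different variables.
    """
    a = make_anchored_fixture(
        n_rows,
        extra_quantitative=("orbitofrontal_Volume", "age"),
        extra_qualitative={"sex": ("M", "F")},
        seed=seed,
    )
    b = make_anchored_fixture(
        n_rows,
        extra_quantitative=("hippocampus_Volume", "updrs_score"),
        extra_qualitative={"handedness": ("L", "R")},
        seed=seed + 1,
    )
    return {"ad_study": a, "pd_study": b}


# ---------------------------------------------------------------------------
# Dirty fixtures with ground-truth QC accounting


@dataclass(frozen=True)
class DefectRates:
    fix: float = 0.0  # fraction of rows given an auto-fixable defect
    drop: float = 0.0  # fraction of rows given an unrepairable defect

    def __post_init__(self) -> None:
        if not (0 <= self.fix <= 1 and 0 <= self.drop <= 1 and self.fix + self.drop <= 1):
            raise ValueError("defect rates must lie in [0,1] and sum to <= 1")


@dataclass(frozen=True)
class DirtyTruth:
    """Ground-truth defect accounting recorded by the generator."""

    n_rows: int
    n_auto_fixable: int
    n_droppable: int


def make_dirty_fixture(
    clean: MarginalTable,
    metas: list[VariableMeta],
    rates: DefectRates,
    seed: int = 0,
) -> tuple[str, TableSchema, DirtyTruth]:
    """Serialize a clean table to CSV, injecting defects at known rates.

    Each row receives at most one defect class.  Auto-fixable injections:
    surrounding whitespace, a thousands separator, or a stripped leading
    FIPS zero.  Droppable injections: a negated count, a non-numeric
    value, or a 6-digit FIPS.  The returned :class:`DirtyTruth` predicts
    the QC report of ``read_marginal_csv`` + ``validate_records`` exactly.
    """
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in metas}
    var_schemas = []
    for m in metas:
        if m.kind == QUANTITATIVE:
            var_schemas.append(VariableSchema(m.name, m.kind, column=m.name, units=m.units))
        else:
            var_schemas.append(
                VariableSchema(
                    m.name, m.kind, category_columns={c: f"{m.name}_{c}" for c in m.categories}
                )
            )
    schema = TableSchema(clean.dataset_label, "fips", tuple(var_schemas))

    header = ["fips"]
    for vs in var_schemas:
        header += [vs.column] if vs.kind == QUANTITATIVE else list(vs.category_columns.values())

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(header)
    n_fix = n_drop = 0
    for geo, row in clean.records.items():
        cells: list[str] = [geo]
        for vs in var_schemas:
            val = row.get(vs.name)
            if vs.kind == QUANTITATIVE:
                cells.append("" if val is None else str(val))
            else:
                for cat in vs.category_columns:
                    cells.append("" if val is None else str(val.get(cat, 0)))
        u = rng.random()
        if u < rates.fix:
            n_fix += 1
            mode = int(rng.integers(3))
            if mode == 0:
                cells[-1] = f"  {cells[-1]} "
            elif mode == 1 and cells[0].startswith("0"):
                cells[0] = cells[0].lstrip("0")
            else:
                # thousands separator inside the first numeric cell >= 1000
                for i in range(1, len(cells)):
                    try:
                        if float(cells[i]) >= 1000 and float(cells[i]).is_integer():
                            s = str(int(float(cells[i])))
                            cells[i] = f"{s[:-3]},{s[-3:]}"
                            break
                    except ValueError:
                        continue
                else:
                    cells[-1] = f" {cells[-1]}"
        elif u < rates.fix + rates.drop:
            n_drop += 1
            mode = int(rng.integers(3))
            count_cols = [
                i
                for i, h in enumerate(header)
                if any(
                    vs.kind == QUALITATIVE and h in vs.category_columns.values()
                    for vs in var_schemas
                )
            ]
            if mode == 0 and count_cols:
                i = count_cols[int(rng.integers(len(count_cols)))]
                cells[i] = "-3"
            elif mode == 1:
                cells[-1] = "not_a_number"
            else:
                cells[0] = cells[0] + "9"
        writer.writerow(cells)
    truth = DirtyTruth(len(clean.records), n_fix, n_drop)
    return buf.getvalue(), schema, truth
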