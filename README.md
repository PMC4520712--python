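# mashboard

Fuse heterogeneous per-county datasets — census demographics, labor
statistics, Medicare charges — into a single privacy-preserving synthetic
population, and interrogate the fused pool through coordinated
(crossfilter-style) multidimensional filters, a REST-style query grammar,
and filtered CSV export. Location-free datasets (e.g. neuroimaging study
exports) join the same machinery through cohort binning on a shared anchor
variable.

The package is the computational back end of a data-mashing dashboard: it
is aimed at health-informatics and open-data practitioners who need to
explore associations across sources that were never designed to be joined,
without ever materializing individual-level records.

## The model

Source tables are *marginals*: for each county `c` (keyed by its 5-digit
FIPS code) a qualitative variable `X` contributes category counts
`n_c(x)`, and a quantitative variable `Y` contributes a single mean
`ȳ_c`. Fusion simulates a 1/`D` population sample (default `D = 1000`):

- county `c` with population `P_c` contributes
  `round_half_up(P_c / D)` samples, each of weight `D` persons;
- each sample in `c` draws `X = x` independently with probability
  `n_c(x) / Σ_x' n_c(x')` (simple random sampling from the county
  distribution);
- each sample in `c` gets `Y = ȳ_c` exactly — the county mean, or the
  state mean if the county's is missing, with no simulated deviation.

A county of 8,000 people with 3,000 males and 5,000 females therefore
becomes 8 samples of which on average 3 are male and 5 female. Because
every attribute is either a shared mean or a fresh draw from an aggregate
distribution, no sample corresponds to a real person and the smallest
representable unit is `D` persons: the pool can be filtered, aggregated
and exported freely without privacy machinery.

Filtering follows the crossfilter convention: all views share one filter
state; predicates (closed intervals on quantitative dimensions, category
sets on qualitative ones) combine by conjunction across dimensions and
disjunction within a category set; and a dimension's own group aggregation
excludes its own predicate, so a brushed view keeps its full axis while
every other view narrows.

## Worked example

```python
import mashboard as mb

table, metas = mb.fixtures.worked_example()   # 1 county: pop 8000, 3000 M / 5000 F
meta = {m.name: m for m in metas}

pool = mb.build_pool(table, "population", scale_denominator=1000, seed=42)
mb.integrate_from_table(pool, table, "gender", meta["gender"], seed=42)

labels = list(pool.values("gender"))
print(pool.size, labels.count("male"), labels.count("female"))
```

prints `8 2 6`: the pool has exactly 8 samples (8000 / 1000), and this
particular seed drew 2 males and 6 females. A single realization
fluctuates binomially around the 3/5 split; averaging the male count over
2,000 replicate integrations gives `3.002` (see
`examples/02_fuse_worked_example.py`), recovering the county marginal.

The other scripts in `examples/` each demonstrate one capability with a
small generated input: QC accounting on a dirtied CSV, coordinated
filtering, the query grammar and export, and the cohort merge of two
location-free study files.

## Command line

A thin CLI wraps the library:

```
mashboard ingest --csv census.csv --schema schema.json --out data/
mashboard summarize data/census.json --out summary.json
mashboard fuse --census data/census.json --pop-var population --seed 1 --out pool.json
mashboard integrate --pool pool.json --dataset data/census.json --var gender
mashboard query --pool pool.json --summary summary.json "gender=male&reqVar=gender"
mashboard export --pool pool.json --state state.json --vars gender -o out.csv
mashboard cohort --spec anchor=cerebellum_Volume,lo=0,hi=300000,n=300 \
    --csv a.csv --csv b.csv --out merged.json
```

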