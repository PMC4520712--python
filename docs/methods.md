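# Methods

## The fusion model

The package represents a mashed multi-source archive by *simulation*
rather than by joined microdata. Each source contributes per-county
marginals only — category counts for qualitative variables, a single mean
for quantitative ones — and the fused object is a pool of weighted
synthetic samples:

- **Pool sizing.** County `c` with population `P_c` contributes
  `round_half_up(P_c / D)` samples at scale denominator `D` (default
  1,000, i.e. each sample represents 1,000 people). The rounding rule is
  half-up per county: for county populations whose remainder mod `D` is
  uniformly distributed this keeps the expected total weight unbiased, and
  it reproduces the exact-division case (8,000 / 1,000 = 8) trivially.
  Total sample weight per county deviates from the county population by at
  most `D/2`.
- **Qualitative integration.** Each sample in county `c` draws category
  `x` independently with probability `n_c(x) / Σ n_c(·)`. Draws are
  independent across samples *and across variables*: no joint distribution
  beyond shared geography is modeled, so cross-variable correlations in
  the pool arise only through county composition. This is deliberate — the
  sources provide marginals, and inventing joint structure (e.g. by
  iterative proportional fitting) would overstate what the data support.
- **Quantitative integration.** Every sample in county `c` carries the
  county mean exactly; if the county mean is absent, the state mean; if
  both are absent, integration fails naming the county. No within-county
  variance is simulated. Within-county sample variance of a quantitative
  variable is therefore exactly zero, which is also the basis of the
  pool's privacy property: no attribute of any sample traces to an
  individual record.
- **Missing qualitative counts** fall back to state-level counts: an
  explicit state record (FIPS `XX000`) if one was ingested, otherwise the
  sum of the state's county-level counts. This mirrors the state-mean
  fallback on the quantitative side.
- **Derived variables** are per-sample arithmetic (`add`, `subtract`,
  `multiply`) over two integrated quantitative variables, registered as
  quantitative with source `"derived"`.

## Seeding

A pool carries one integer seed. Each integration draws from a dedicated
generator seeded by the tuple *(seed, CRC-32 of the variable name, county
FIPS as integer)* via numpy's `SeedSequence`. Consequences: (a) two runs
with equal seeds are attribute-identical; (b) integrating variables lazily
(on demand, as an interactive front end would) or eagerly, in any order,
yields identical pools; (c) county iteration order is irrelevant. CRC-32
is used rather than Python's `hash` because it is stable across processes.

## Quality control

The ingest QC policy is a closed list. Auto-fixed: surrounding whitespace,
thousands separators, short FIPS codes (zero-padded to width 5). Dropped:
non-numeric or negative or non-integral counts, non-finite numbers, FIPS
longer than 5 digits or non-numeric. Accounting is per row — a row is
counted once as fixed or once as dropped — so
`n_input_rows = survivors + n_dropped` holds exactly and validation is
idempotent (a second pass reports zero errors). There is no interactive
repair channel: anything outside the fix list is dropped and logged, which
keeps the pipeline deterministic. Missing-value tokens (empty string,
`NA`, `n/a`, `NaN`, case-insensitive) mark a value as absent, which is not
a defect: absent values are served by the fallback rules at fusion time.
Rows whose FIPS ends in `000` are state-level records and are routed to
the table's state fallbacks rather than treated as counties.

## Filter engine

Correctness is defined by a naive full scan: a sample passes an interval
predicate `[lo, hi]` iff `lo ≤ v ≤ hi` (closed ends, missing fails), a
category predicate iff its label is in the set. The engine maintains a
sorted index per quantitative dimension (interval masks by binary search)
and a categorical code index per qualitative dimension, so re-filtering
does not rescan values; the test suite asserts exact agreement with the
scan on a thousand randomized pools. Group aggregation over a dimension
applies every predicate *except* that dimension's own — the one semantic
choice with ecosystem precedent, letting a brushed view keep its full
axis. Quantitative grouping uses half-open bins with the final bin closed
at the top edge (the same convention as cohort binning), or one group per
distinct value when no bins are given. Configured limits default to 30
simultaneous views and 1–6 variables per view.

## Query grammar and export

`var[min]=v` / `var[max]=v` give inclusive bounds on quantitative
variables (consistent with the engine's closed intervals); repeated
`var=label` pairs union into a category set; `reqVar=name` appends to the
projection list, and several `reqVar`s are allowed. Bare `name=value` on a
quantitative variable is rejected rather than guessed at. Percent- and
form-encoding (`+` as space) are decoded by the standard library. Query
execution routes through the same filter engine as the interactive path,
and export emits exactly the selected rows with the displayed columns plus
the sample weight, so API, engine and export agree row for row.

## Cohort binning

A cohort spec is an anchor column, a range `[lo, hi]` and a count `n`.
Edges are computed as `lo + i·(hi − lo)/n` directly from the range (no
cumulative addition, so `edge(n) == hi` exactly); values bin into
half-open intervals with the final bin closed, out-of-range and missing
anchors are dropped with a count. Variable kinds are inferred from the
entries alone: quantitative iff every non-missing entry parses as a finite
number. Merging concatenates the cohort-assigned datasets with columns
prefixed by dataset label (the shared anchor keeps its name); the cohort
index plays the county's role, each record keeps weight 1 (these are real
rows, not scaled samples), and the merged pool feeds the filter engine
unchanged. Records from different source files never join into one row —
cross-dataset filters interact through cohort membership only.

## Synthetic data

The fixture generators emulate the *shape* of the real inputs, not their
statistics: county tables draw populations uniformly, category proportions
from a flat Dirichlet, and means uniformly within a range; anchored pairs
draw the anchor uniformly over [0, 300,000] with a couple of quantitative
and categorical companions. Passing tests therefore demonstrate the
correctness of the pipeline's mechanics (sizing, marginal recovery, QC
accounting, filter/query/export agreement), not fidelity to any real
demographic joint distribution, which the marginal-only model does not
attempt anyway. The dirty-fixture generator injects at most one defect per
row, recording ground truth that must match the QC report exactly.

## Problem sizes and tolerances

Monte-Carlo checks assert agreement within 4 standard errors: the
worked-example recovery uses 10,000 replicate integrations of an 8-sample
pool (SE of the mean male count ≈ 0.0137); general marginal recovery uses
1,000 replicates of a 40-sample pool. Oracle-equivalence sweeps use 1,000
randomized pools of up to 500 samples and 6 dimensions, and 500 randomized
query specs; these are exact (no tolerance). Floating-point group
aggregates are compared at relative tolerance 1e-12 to allow for summation
order.

## Known limitations

- No joint-distribution calibration across variables; correlations beyond
  county composition are not representable.
- ZIP-code anchoring is not implemented; geography is FIPS-only.
- Quantitative variables have no within-county spread, so variance-based
  statistics within a county are degenerate by design.
- The query layer is a library plus CLI; an HTTP wrapper would be thin
  glue but is not included.
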