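"""Ingest a county marginal CSV with injected defects and account for QC.

Generates a clean 30-county table, dirties 20% of its rows (half
auto-fixable, half unrepairable), then runs the read + validate pipeline
and compares the QC report against the generator's ground truth.
"""

import io

import mashboard as mb
from mashboard.fixtures import DefectRates, FixtureConfig

clean, metas = mb.fixtures.make_county_fixture(FixtureConfig(n_counties=30, seed=1))
csv_text, schema, truth = mb.fixtures.make_dirty_fixture(
    clean, metas, DefectRates(fix=0.10, drop=0.10), seed=1
)

raw = mb.read_marginal_csv(io.StringIO(csv_text), schema)
validated, report = mb.validate_records(raw)

print(f"rows in           : {report.n_input_rows}")
print(f"auto-fixed        : {report.n_auto_fixed}  (generator injected {truth.n_auto_fixable})")
print(f"dropped           : {report.n_dropped}  (generator injected {truth.n_droppable})")
print(f"error rate        : {report.error_rate:.3f}")
print(f"counties surviving: {len(validated.records)}")
# The error rate counts every touched row, fixed or dropped, over all input
# rows; the survivors satisfy every invariant of a clean marginal table.
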