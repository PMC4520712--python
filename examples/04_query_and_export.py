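"""The machine-facing query grammar and the export-tile semantics.

`var[min]=v` / `var[max]=v` bound quantitative variables, repeated
`var=label` pairs union into a category set, and `reqVar=name` names the
returned variables.  Export produces the CSV equivalent of the same
request: filtered rows, displayed columns, plus the sample weight.
"""

import mashboard as mb
from mashboard.fixtures import FixtureConfig

table, metas = mb.fixtures.make_county_fixture(FixtureConfig(n_counties=8, seed=4))
pool = mb.build_pool(table, "population", seed=4)
for m in metas:
    if m.name != "population":
        mb.integrate_from_table(pool, table, m.name, m, seed=4)
summary = mb.build_summary([(table, metas)])

q = "income_per_capita[min]=30000&gender=male&reqVar=income_per_capita&reqVar=gender"
spec = mb.parse_query(q, summary)
result = mb.execute_query(pool, spec)
print(f"query  : {q}")
print(f"matches: {len(result)} samples")
print(result.head(4))

state = spec.to_filter_state()
csv_text = mb.export_csv(pool, state, ["gender", "income_per_capita"])
print("\nexport (first 3 lines):")
print("\n".join(csv_text.splitlines()[:3]))
# The export rows are exactly the API result for the equivalent query; the
# weight column records how many people each synthetic sample represents.
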