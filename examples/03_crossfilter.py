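"""Coordinated filtering: one shared selection, own-filter-excluded groups.

Selecting 'male' on a gender view narrows every other view to male samples,
while the gender view itself keeps showing both categories at their
unfiltered counts — the crossfilter convention that lets a brushed chart
keep its full axis.
"""

import mashboard as mb
from mashboard.fixtures import FixtureConfig

table, metas = mb.fixtures.make_county_fixture(FixtureConfig(n_counties=8, seed=4))
pool = mb.build_pool(table, "population", seed=4)
for m in metas:
    if m.name != "population":
        mb.integrate_from_table(pool, table, m.name, m, seed=4)

engine = mb.FilterEngine(pool)
gender = engine.add_dimension("gender")
income = engine.add_dimension("income_per_capita")

state = mb.FilterState()
print(f"pool size                    : {pool.size}")
print(f"gender counts, no filters    : {engine.group_aggregate(gender, state)}")

state = mb.set_filter(state, gender, mb.CategorySet({"male"}))
print(f"selection after gender=male  : {len(engine.current_selection(state))}")
print(f"gender view (own filter off) : {engine.group_aggregate(gender, state)}")

bins = [15000, 30000, 45000, 60000, 75000]
print(f"male income histogram        : {engine.group_aggregate(income, state, bins=bins)}")
# The gender view still reports both categories (its own filter is
# excluded); the income histogram counts only male samples.
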