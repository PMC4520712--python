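import pytest

import mashboard as mb


@pytest.fixture(scope="session")
def worked():
    """The canonical single-county table: pop 8,000; 3,000 male / 5,000 female."""
    table, metas = mb.fixtures.worked_example()
    return table, {m.name: m for m in metas}


@pytest.fixture()
def toy_census():
    """A clean multi-county marginal table with one qual + two quant variables."""
    cfg = mb.fixtures.FixtureConfig(n_counties=6, seed=11)
    table, metas = mb.fixtures.make_county_fixture(cfg)
    return table, metas


@pytest.fixture()
def fused_pool(toy_census):
    """A pool with gender, income and population marginals fully integrated."""
    table, metas = toy_census
    pool = mb.build_pool(table, "population", scale_denominator=1000, seed=5)
    for m in metas:
        if m.name != "population":
            mb.integrate_from_table(pool, table, m.name, m, seed=5)
    return pool
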