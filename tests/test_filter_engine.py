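"""Crossfilter semantics: shared selection, own-filter-excluded grouping."""

import numpy as np
import pytest

import mashboard as mb
from _naive import (
    groups_equal,
    naive_group,
    naive_selection,
    random_pool,
    random_predicates,
    random_stat,
)


@pytest.fixture()
def engine(fused_pool):
    eng = mb.FilterEngine(fused_pool)
    eng.add_dimension("gender")
    eng.add_dimension("income_per_capita")
    return eng


class TestDimensions:
    def test_adding_a_dimension_never_changes_selection(self, fused_pool):
        eng = mb.FilterEngine(fused_pool)
        before = eng.current_selection(mb.FilterState())
        eng.add_dimension("gender")
        after = eng.current_selection(mb.FilterState())
        assert len(before) == len(after) == fused_pool.size

    def test_view_limit_enforced(self, fused_pool):
        for i in range(29):  # fused_pool starts with 2 integrated variables
            mb.derive_variable(
                fused_pool, f"d{i}", "income_per_capita", "add", "income_per_capita"
            )
        eng = mb.FilterEngine(fused_pool)
        variables = list(fused_pool.integrated)
        for var in variables[:30]:
            eng.add_dimension(var)
        with pytest.raises(mb.LimitError):
            eng.add_dimension(variables[30])

    def test_vars_per_view_limit(self, engine):
        engine.validate_view(["gender"])
        with pytest.raises(mb.LimitError):
            engine.validate_view([f"v{i}" for i in range(7)])
        with pytest.raises(mb.LimitError):
            engine.validate_view([])

    def test_unintegrated_variable_rejected(self, fused_pool):
        with pytest.raises(mb.FilterError, match="never_seen"):
            mb.FilterEngine(fused_pool).add_dimension("never_seen")


class TestSetFilter:
    def test_category_filter_restricts_to_members(self, engine, fused_pool):
        dim = engine.dimensions["gender"]
        state = mb.set_filter(mb.FilterState(), dim, mb.CategorySet({"male"}))
        ids = engine.current_selection(state)
        assert len(ids) > 0
        assert (fused_pool.data.loc[ids, "gender"] == "male").all()

    def test_clearing_restores_prior_selection(self, engine):
        dim = engine.dimensions["income_per_capita"]
        empty = mb.FilterState()
        before = engine.current_selection(empty)
        state = mb.set_filter(empty, dim, mb.Interval(40_000, 60_000))
        restored = engine.current_selection(mb.clear_filter(state, dim))
        assert np.array_equal(before, restored)

    def test_replacement_semantics_last_interval_wins(self, engine):
        dim = engine.dimensions["income_per_capita"]
        state = mb.set_filter(mb.FilterState(), dim, mb.Interval(0, 1))
        state = mb.set_filter(state, dim, mb.Interval(0, 1e9))
        only_last = mb.set_filter(mb.FilterState(), dim, mb.Interval(0, 1e9))
        assert np.array_equal(
            engine.current_selection(state), engine.current_selection(only_last)
        )

    def test_predicate_type_must_match_dimension_kind(self, engine):
        with pytest.raises(mb.FilterError):
            mb.set_filter(mb.FilterState(), engine.dimensions["gender"], mb.Interval(0, 1))
        with pytest.raises(mb.FilterError):
            mb.set_filter(
                mb.FilterState(),
                engine.dimensions["income_per_capita"],
                mb.CategorySet({"male"}),
            )

    def test_interval_requires_ordered_bounds(self):
        with pytest.raises(mb.FilterError):
            mb.Interval(2, 1)
        with pytest.raises(mb.FilterError):
            mb.CategorySet(set())


class TestGroupAggregate:
    def test_unfiltered_counts_partition_the_pool(self, engine, fused_pool):
        groups = engine.group_aggregate(engine.dimensions["gender"], mb.FilterState())
        assert sum(groups.values()) == fused_pool.size

    def test_own_filter_excluded_from_own_grouping(self, engine):
        dim = engine.dimensions["gender"]
        unfiltered = engine.group_aggregate(dim, mb.FilterState())
        state = mb.set_filter(mb.FilterState(), dim, mb.CategorySet({"male"}))
        assert engine.group_aggregate(dim, state) == unfiltered

    def test_other_dimension_filter_applies(self, engine, fused_pool):
        gdim = engine.dimensions["gender"]
        idim = engine.dimensions["income_per_capita"]
        state = mb.set_filter(mb.FilterState(), gdim, mb.CategorySet({"male"}))
        groups = engine.group_aggregate(idim, state)
        preds = {"gender": mb.CategorySet({"male"})}
        assert groups_equal(groups, naive_group(fused_pool, "income_per_capita", preds))

    def test_stat_over_qualitative_target_rejected(self, engine):
        with pytest.raises(mb.FilterError, match="gender"):
            engine.group_aggregate(
                engine.dimensions["income_per_capita"], mb.FilterState(), ("mean", "gender")
            )


class TestOracleEquivalence:
    """The naive full-scan defines correctness for selection and grouping."""

    N_POOLS = 120  # the full 1,000-pool sweep runs in the acceptance suite

    def test_randomized_pools_match_naive_scan(self):
        rng = np.random.default_rng(202)
        for _ in range(self.N_POOLS):
            pool = random_pool(rng, max_samples=120)
            preds = random_predicates(rng, pool)
            eng = mb.FilterEngine(pool)
            state = mb.FilterState()
            for var, p in preds.items():
                state = mb.set_filter(state, eng.add_dimension(var), p)
            assert eng.current_selection(state).tolist() == naive_selection(pool, preds)
            if preds:
                var = list(preds)[int(rng.integers(len(preds)))]
            else:
                var = list(pool.integrated)[0]
            stat = random_stat(rng, pool)
            got = eng.group_aggregate(eng.add_dimension(var), state, stat)
            assert groups_equal(got, naive_group(pool, var, preds, stat))

    def test_binned_grouping_matches_naive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pool = random_pool(rng, max_samples=100)
            quant = [v for v, m in pool.integrated.items() if m.kind == mb.QUANTITATIVE]
            if not quant:
                continue
            var = quant[0]
            preds = random_predicates(rng, pool)
            eng = mb.FilterEngine(pool)
            state = mb.FilterState()
            for v, p in preds.items():
                state = mb.set_filter(state, eng.add_dimension(v), p)
            bins = [0.0, 25.0, 50.0, 75.0, 100.0]
            got = eng.group_aggregate(eng.add_dimension(var), state, bins=bins)
            assert groups_equal(got, naive_group(pool, var, preds, bins=bins))


class TestStateAlgebra:
    def test_adding_predicates_never_enlarges_selection(self, engine):
        gdim = engine.dimensions["gender"]
        idim = engine.dimensions["income_per_capita"]
        state = mb.FilterState()
        sizes = [len(engine.current_selection(state))]
        state = mb.set_filter(state, gdim, mb.CategorySet({"female"}))
        sizes.append(len(engine.current_selection(state)))
        state = mb.set_filter(state, idim, mb.Interval(20_000, 40_000))
        sizes.append(len(engine.current_selection(state)))
        assert sizes == sorted(sizes, reverse=True)
        cleared = mb.clear_filter(state, idim)
        assert len(engine.current_selection(cleared)) >= sizes[-1]

    def test_partition_property(self, engine):
        # group counts over a dimension (own filter excluded) sum to the
        # selection size under the other filters alone
        gdim = engine.dimensions["gender"]
        idim = engine.dimensions["income_per_capita"]
        state = mb.set_filter(mb.FilterState(), gdim, mb.CategorySet({"male"}))
        state = mb.set_filter(state, idim, mb.Interval(20_000, 50_000))
        groups = engine.group_aggregate(gdim, state)
        others_only = mb.clear_filter(state, gdim)
        assert sum(groups.values()) == len(engine.current_selection(others_only))

    def test_incremental_equals_from_scratch(self, engine):
        gdim = engine.dimensions["gender"]
        idim = engine.dimensions["income_per_capita"]
        s = mb.FilterState()
        s = mb.set_filter(s, gdim, mb.CategorySet({"male"}))
        s = mb.set_filter(s, idim, mb.Interval(0, 5e4))
        s = mb.clear_filter(s, gdim)
        s = mb.set_filter(s, gdim, mb.CategorySet({"female"}))
        s = mb.set_filter(s, idim, mb.Interval(1e4, 9e4))
        rebuilt = mb.FilterState(
            {"gender": mb.CategorySet({"female"}), "income_per_capita": mb.Interval(1e4, 9e4)}
        )
        assert np.array_equal(
            engine.current_selection(s), engine.current_selection(rebuilt)
        )

    def test_state_serialization_round_trip(self):
        state = mb.FilterState(
            {"gender": mb.CategorySet({"male"}), "income": mb.Interval(1.5, 2.5)}
        )
        back = mb.FilterState.from_json_dict(state.to_json_dict())
        assert dict(back) == dict(state)
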