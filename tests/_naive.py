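"""Naive full-scan reference implementations used as oracles.

These deliberately share no code with the engine under test: plain Python
loops over the pool's rows define the correct answer for selection and
group aggregation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from mashboard import CategorySet, Interval, SamplePool, QUALITATIVE, QUANTITATIVE


def _passes(value, predicate) -> bool:
    if isinstance(predicate, Interval):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        return predicate.lo <= value <= predicate.hi
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return value in predicate.labels


def _rows(pool: SamplePool):
    return zip(pool.data.index.tolist(), pool.data.to_dict("records"))


def naive_selection(pool: SamplePool, predicates: dict) -> list[int]:
    out = []
    for sid, row in _rows(pool):
        if all(_passes(row[var], p) for var, p in predicates.items()):
            out.append(int(sid))
    return out


def naive_group(pool: SamplePool, group_var: str, predicates: dict, stat="count", bins=None):
    external = {v: p for v, p in predicates.items() if v != group_var}
    kind = pool.kind_of(group_var)
    col = pool.data[group_var]

    def keys_of(value):
        if kind == QUALITATIVE:
            return None if value is None else value
        if isinstance(value, float) and math.isnan(value):
            return None
        if bins is None:
            return float(value)
        if value < bins[0] or value > bins[-1]:
            return None
        for i in range(len(bins) - 1):
            if bins[i] <= value < bins[i + 1]:
                return (float(bins[i]), float(bins[i + 1]))
        return (float(bins[-2]), float(bins[-1]))  # value == top edge

    # enumerate every group key, even empty ones, like a chart axis would
    groups: dict = {}
    if kind == QUALITATIVE:
        seen = []
        for v in col:
            if v is not None and v not in seen:
                seen.append(v)
        for v in seen:
            groups[v] = []
    elif bins is None:
        for v in sorted({float(v) for v in col if not math.isnan(v)}):
            groups[v] = []
    else:
        for i in range(len(bins) - 1):
            groups[(float(bins[i]), float(bins[i + 1]))] = []

    for sid, row in _rows(pool):
        if not all(_passes(row[v], p) for v, p in external.items()):
            continue
        k = keys_of(row[group_var])
        if k is not None:
            groups[k].append(sid)

    out = {}
    for k, ids in groups.items():
        if stat == "count":
            out[k] = len(ids)
        else:
            op, var = stat
            vals = [float(pool.data.at[i, var]) for i in ids]
            if not vals:
                out[k] = float("nan")
            elif op == "sum":
                out[k] = float(sum(vals))
            else:
                out[k] = float(sum(vals)) / len(vals)
    return out


def groups_equal(a: dict, b: dict) -> bool:
    if set(a) != set(b):
        return False
    for k in a:
        x, y = a[k], b[k]
        both_nan = (
            isinstance(x, float) and isinstance(y, float)
            and math.isnan(x) and math.isnan(y)
        )
        if not both_nan and not math.isclose(float(x), float(y), rel_tol=1e-12, abs_tol=0.0):
            return False
    return True


# ---------------------------------------------------------------------------
# Randomized small pools and filter states


_GEOS = ["01001", "01003", "26161", "36061"]
_CATEGORIES = ["A", "B", "C", "D"]


def random_pool(rng: np.random.Generator, max_samples=500, max_dims=6) -> SamplePool:
    from mashboard import VariableMeta

    n = int(rng.integers(10, max_samples + 1))
    n_vars = int(rng.integers(1, max_dims + 1))
    data = {"geo_id": rng.choice(_GEOS, size=n)}
    metas = {}
    for j in range(n_vars):
        name = f"v{j}"
        if rng.random() < 0.5:
            k = int(rng.integers(2, len(_CATEGORIES) + 1))
            cats = _CATEGORIES[:k]
            vals = [str(c) for c in rng.choice(cats, size=n)]
            if rng.random() < 0.3:  # sprinkle missing labels
                for i in rng.choice(n, size=max(1, n // 20), replace=False):
                    vals[i] = None
            data[name] = pd.Series(vals, dtype=object)
            metas[name] = VariableMeta(name, "rand", QUALITATIVE, tuple(cats))
        else:
            vals = np.round(rng.uniform(0, 100, size=n), 1)
            if rng.random() < 0.3:
                vals[rng.choice(n, size=max(1, n // 20), replace=False)] = np.nan
            data[name] = vals
            metas[name] = VariableMeta(name, "rand", QUANTITATIVE)
    return SamplePool(pd.DataFrame(data), scale_denominator=1000, rng_seed=0, integrated=metas)


def random_predicates(rng: np.random.Generator, pool: SamplePool) -> dict:
    preds = {}
    for var, meta in pool.integrated.items():
        if rng.random() < 0.6:
            continue
        if meta.kind == QUALITATIVE:
            cats = list(meta.categories)
            k = int(rng.integers(1, len(cats) + 1))
            preds[var] = CategorySet(rng.choice(cats, size=k, replace=False).tolist())
        else:
            lo, hi = sorted(rng.uniform(-10, 110, size=2))
            preds[var] = Interval(float(lo), float(hi))
    return preds


def random_stat(rng: np.random.Generator, pool: SamplePool):
    quant = [v for v, m in pool.integrated.items() if m.kind == QUANTITATIVE]
    r = rng.random()
    if not quant or r < 0.5:
        return "count"
    return ("sum" if r < 0.75 else "mean", quant[int(rng.integers(len(quant)))])
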