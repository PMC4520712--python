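"""Fuse the canonical one-county example into a synthetic sample pool.

A county of 8,000 people (3,000 male / 5,000 female) at 1/1,000 scale
becomes 8 samples, each standing for 1,000 people.  Gender is assigned by
simple random sampling from the county's distribution, so across many
seeded replicates the pool averages 3 male and 5 female samples.
"""

import mashboard as mb

table, metas = mb.fixtures.worked_example()
meta = {m.name: m for m in metas}

pool = mb.build_pool(table, "population", scale_denominator=1000, seed=42)
print(f"samples in pool : {pool.size}  (population 8000 / scale 1000)")

mb.integrate_from_table(pool, table, "gender", meta["gender"], seed=42)
labels = list(pool.values("gender"))
print(f"one realization : {labels.count('male')} male / {labels.count('female')} female")

reps, male = 2000, 0
for r in range(reps):
    p = mb.build_pool(table, "population", seed=r)
    mb.integrate_from_table(p, table, "gender", meta["gender"], seed=r)
    male += int((p.values("gender") == "male").sum())
print(f"mean over {reps} replicates: {male / reps:.3f} male (expected 3 = 8 * 3000/8000)")
# Any single realization fluctuates binomially; the replicate mean recovers
# the county marginal, which is the fusion contract.
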