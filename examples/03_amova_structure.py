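"""Hierarchical AMOVA and pairwise F_ST on a two-basin scenario.

Partitions genetic variance into between-basin / among-estuaries-within-
basin / within-estuary components with permutation tests, then computes
pairwise F_ST between estuaries.
"""

import numpy as np

from haplopop import amova, pairwise_fst
from haplopop.simulate import EstuarySpec, ScenarioConfig, generate

ests = ([EstuarySpec(f"G{i}", "gulf", i * 150.0, 15) for i in range(3)]
        + [EstuarySpec(f"A{i}", "atlantic", 2000 + i * 150.0, 15) for i in range(3)])
ds, _ = generate(ScenarioConfig(estuaries=ests, n_loci=120, frac_env_loci=0.0,
                                seed=11))
rng = np.random.default_rng(0)
res = amova(ds.genotypes, ds.estuary_of(), groups=ds.basin_of(), n_perm=499,
            rng=rng)
print(res.table.round(4).to_string(index=False))
print("F-statistics:", {k: round(v, 4) for k, v in res.f_statistics.items()})
print("permutation p:", {k: round(v, 4) for k, v in res.p_values.items()})

pw = pairwise_fst(ds.genotypes, ds.estuary_of(), n_perm=199, rng=rng)
print("\npairwise F_ST (BH-adjusted q in parentheses where q < 0.05):")
print(pw.fst.round(4).to_string())
# Expect F_CT (between basins) to dwarf F_SC, with cross-basin pairs the
# only significant pairwise comparisons.
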