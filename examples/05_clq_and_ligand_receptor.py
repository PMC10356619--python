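"""Colocalization quotients and colocalization-guided ligand-receptor
nomination with permutation validation.

CLQ(A->B) > 1 means type B is over-represented among the 10 nearest
neighbours of type A cells.  The cohort plants a colon-only plasma-to-TA
attraction; the expression generator plants matching ligand/receptor fold
changes, which the nomination and validation steps should recover.
"""

from histoarch.colocalization import (
    clq, clq_group_test, lr_differential, success_rate_permutation,
)
from histoarch.synthetic import (
    default_cohort_config, default_expression_config, generate_cohort,
    generate_expression, lr_pair_table,
)

maps, _ = generate_cohort(default_cohort_config(n_donors=3, intensity=0.005,
                                                seed=5))
mats = [clq(m, 10) for m in maps]
test = clq_group_test(mats, {m.sample_id: m.group for m in maps})
row = test.set_index(["pair_a", "pair_b"]).loc[("plasma", "TA")]
print(f"CLQ(plasma->TA): SB {row['mean_SB']:.2f}, CL {row['mean_CL']:.2f}, "
      f"adjusted p = {row['p_adj']:.2e} ({row['direction']})")
print("The colon-only attraction shows as excess TA cells near plasma "
      "cells in CL only.\n")

cfg = default_expression_config(n_genes=100, n_planted=10, log2fc=1.5,
                                cells_per_arm=2000)
adata = generate_expression(cfg, seed=6)
nom = lr_differential(adata, lr_pair_table(cfg), [("plasma", "TA")])
hits = nom[nom["nominated"]]
print(f"nominated {len(hits)} ligand-receptor pairs "
      f"(10 were planted with log2FC = +1.5 in CL):")
print(hits[["ligand", "receptor", "ligand_log2fc", "receptor_log2fc"]]
      .round(2).head(10).to_string(index=False))

val = generate_expression(default_expression_config(
    n_genes=100, n_planted=10, cells_per_arm=500), seed=7)
res = success_rate_permutation(val, hits, n_permutations=2000, seed=8)
print(f"\nvalidation: {res.observed_successes}/{res.n_predictions} "
      f"predictions replicate ({100 * res.success_rate:.1f}%), "
      f"gene-label permutation p = {res.p_value:.2e}")
print("A small p means the replicated fraction far exceeds what arbitrary "
      "gene relabelling achieves.")
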