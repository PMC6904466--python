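"""Differential expression ranking and weighted gene-set enrichment.

Simulates a 3-vs-3 count experiment in which a planted gene set is
up-regulated, ranks every gene by pi = phi * (-log10 pv) (log2 fold-change
times log-significance from the per-gene NB likelihood-ratio test), and
tests whether the planted set is enriched at the top of the ranking.
"""
import numpy as np

import pathtune as pt

rng = np.random.default_rng(42)
planted = [f"G{i + 1:04d}" for i in range(15)]
plan = pt.SimulationPlan(
    condition_log2fc_effects={g: 2.0 for g in planted},
)
cond = np.array([0, 0, 0, 1, 1, 1])
counts, truth = pt.simulate_counts(plan, 300, cond, rng=rng)

ranked = pt.differential_rank_table(counts, cond)
print(f"ranked {len(ranked)} genes; top 3 by pi:")
for g in ranked[:3]:
    print(f"  {g.gene_id}: phi={g.phi:+.2f} pv={g.pv:.2e} pi={g.pi:+.1f}")

res = pt.gsea_test(ranked, pt.GeneSet("planted", frozenset(planted)),
                   n_perm=5_000, seed=1)
p_text = f"{res.p_perm:.4g}" if not res.p_is_bound else f"< {1 / res.n_perm:g}"
print(f"\nGSEA: ES={res.es:.3f} NES={res.nes:.3f} p={p_text}")
print("A positive ES near 1 means the planted set concentrates at the very")
print("top of the ranking; p is the fraction of random same-size sets with")
print("an equally extreme same-sign score.")
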