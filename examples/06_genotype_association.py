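"""Genotype-stratified expression association and paired comparison.

Simulates counts whose mean rises 2-fold per alternate allele for one gene,
fits the negative-binomial GLM against the 0/1/2 dosage, and tests it by
likelihood ratio against an intercept-only model (chi-square, df=1). Also
runs the paired signed-rank comparison on a planted tumour/normal design.
"""
import numpy as np

import pathtune as pt

rng = np.random.default_rng(42)
n = 150
genotype = rng.integers(0, 3, n)

plan = pt.SimulationPlan(genotype_log2fc_effects={"G0001": 1.0})
counts, _ = pt.simulate_counts(plan, 50, np.zeros(n), genotypes=genotype,
                               rng=rng)
offsets = np.log(pt.size_factors(counts))

for gid in ["G0001", "G0002"]:
    res = pt.lrt_genotype(counts.loc[gid].to_numpy(), genotype,
                          offsets=offsets)
    print(f"{gid}: beta1={res.beta1:+.3f} (log scale), "
          f"LRT={res.lrt_stat:.1f}, df={res.df}, p={res.p_chi2:.3g}")
print("G0001 carries the planted effect (beta1 ~ ln 2 = 0.69 per allele);")
print("G0002 is null, so its p should be unremarkable.\n")

# paired tumour/normal comparison
n_pairs = 25
tumour = rng.negative_binomial(20, 20 / (20 + 400.0), n_pairs)
normal = rng.negative_binomial(20, 20 / (20 + 200.0), n_pairs)
res = pt.paired_test(tumour.astype(float), normal.astype(float))
print(f"paired signed-rank on {res.n_pairs_used} informative pairs: "
      f"p={res.pvalue:.3g}")
print("The planted 2-fold induction in tumours is detected.")
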