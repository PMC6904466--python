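"""The whole analysis in one call: simulate -> clump -> consensus ->
permutation tests -> gene assignment -> GSEA -> genotype association.

Equivalent to `pathtune simulate` followed by `pathtune run`.
"""
from pathlib import Path

import pathtune as pt
from pathtune.pipeline import RunConfig, run_full, summarize

out = Path("example_output")
bundle = pt.write_dataset(pt.SimulationPlan(), out / "dataset", seed=42)
paths = bundle["paths"]

cfg = RunConfig(
    genome=str(paths["genome"]),
    stats=str(paths["stats"]),
    panel=str(paths["panel_dosage"]),
    peak_beds=[str(p) for p in paths["peak_sets"]],
    enhancers=str(paths["enhancers"]),
    genes=str(paths["genes"]),
    interactions=str(paths["interactions"]),
    counts_condition=str(paths["counts_condition"]),
    samples_condition=str(paths["samples_condition"]),
    counts_genotype=str(paths["counts_genotype"]),
    samples_genotype=str(paths["samples_genotype"]),
    counts_paired=str(paths["counts_paired"]),
    samples_paired=str(paths["samples_paired"]),
    seed=7,
    n_iter=100_000,
    outdir=str(out / "run"),
)
report = run_full(cfg)
print(summarize(report, outdir=out / "run"))
print(f"\nfull report: {out / 'run' / 'report.json'}")
print(f"figures:     {out / 'run'}/null_*.svg, gsea_running_sum.svg")
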