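"""Consensus peaks across replicate datasets, and locus-to-gene assignment.

A binding site is accepted when peaks from two or more datasets overlap by
at least one base pair; the consensus interval is the union span of the
cluster. Genes are assigned to a locus if they lie within 25 kb, or if
their promoter (TSS +/- 2 kb) is touched by a long-range chromatin
interaction anchored at the locus — demonstrated here on the published
13-locus table, realised in synthetic coordinates.
"""
import numpy as np

import pathtune as pt

# consensus on simulated replicate peak calls
plan = pt.SimulationPlan()
genome = pt.make_genome(plan)
rng = np.random.default_rng(42)
panel = pt.simulate_panel(plan, genome, rng)
peaks, _ = pt.simulate_features(plan, genome, panel, rng)
replicates = pt.simulate.replicate_peak_sets(plan, peaks, genome, rng)
consensus = pt.consensus_peaks(replicates, min_datasets=2)
print(f"{len(consensus)} consensus sites from "
      f"{sum(len(r) for r in replicates)} peaks in {len(replicates)} "
      f"datasets (true sites: {len(peaks)})")

# gene assignment on the published table's realization
r = pt.table1_fixture().realize()
print("\nper-locus gene assignment (25 kb + promoter interaction):")
for locus in r["loci"]:
    genes = sorted(pt.assign_genes(locus, r["genes"], r["interactions"]))
    print(f"  {locus.name:9s} -> {', '.join(genes) if genes else '-'}")
print("\n2p21 gains EPAS1 only through the long-range interaction: its")
print("promoter is 200 kb from the locus, far beyond the 25-kb window.")
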