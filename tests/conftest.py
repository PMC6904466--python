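import numpy as np
import pandas as pd
import pytest

import pathtune as pt


@pytest.fixture(scope="session")
def small_plan():
    """Scaled-down plan for fast end-to-end tests."""
    return pt.SimulationPlan(
        chrom_lengths=(3_000_000, 3_000_000),
        n_samples=60,
        n_snps=600,
        snps_per_block=6,
        n_causal_in_peaks=3,
        n_causal_outside=3,
        peak_count=40,
        enhancer_count=80,
        n_genes=120,
    )


@pytest.fixture(scope="session")
def small_bundle(small_plan, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    return pt.write_dataset(small_plan, outdir, seed=11)


@pytest.fixture(scope="session")
def table1_realization():
    return pt.table1_fixture().realize()


def make_panel(dosages, positions=None, chroms=None, ids=None):
    """Hand-built panel from a samples x SNPs dosage array."""
    dosages = np.asarray(dosages)
    n = dosages.shape[1]
    return pt.GenotypePanel(
        dosages,
        ids if ids is not None else [f"s{i + 1}" for i in range(n)],
        chroms if chroms is not None else ["chr1"] * n,
        positions if positions is not None else list(range(100, 100 + n)),
    )


def make_stats(rows):
    """rows: (chrom, pos, snp_id, pvalue) tuples."""
    return pt.SummaryStats(
        pd.DataFrame(rows, columns=["chrom", "pos", "snp_id", "pvalue"])
    )


def make_locus(chrom, member_pos, name="L", tier="supra", pvalue=1e-10):
    member_pos = tuple(sorted(member_pos))
    ids = tuple(f"{name}_m{i}" for i in range(len(member_pos)))
    return pt.RiskLocus(
        name=name, chrom=chrom, index_snp=ids[0], index_pos=member_pos[0],
        index_pvalue=pvalue, member_ids=ids, member_pos=member_pos, tier=tier,
    )
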