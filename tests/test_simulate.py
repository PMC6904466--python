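"""The synthetic-data generator: genome layout, LD panel, planted GWAS,
count matrices, and full-dataset determinism and round-trips."""
import filecmp
from pathlib import Path

import numpy as np
import pytest

import pathtune as pt
from pathtune.errors import PlanError, SizingError
from pathtune.simulate import replicate_peak_sets


class TestPlanAndGenome:
    def test_two_chromosomes_of_one_mb(self):
        plan = pt.SimulationPlan(chrom_lengths=(1_000_000, 1_000_000),
                                 n_snps=100, snps_per_block=5,
                                 peak_count=5, enhancer_count=5,
                                 n_causal_in_peaks=1, n_causal_outside=1)
        genome = pt.make_genome(plan)
        assert genome.chrom_names == ("chr1", "chr2")
        assert genome.chrom_lengths == (1_000_000, 1_000_000)

    def test_same_plan_same_layout(self):
        plan = pt.SimulationPlan()
        assert pt.make_genome(plan) == pt.make_genome(plan)

    def test_infeasible_footprint_errors(self):
        plan = pt.SimulationPlan(chrom_lengths=(50_000,), n_snps=100,
                                 snps_per_block=5, ld_block_len=25_000)
        with pytest.raises(SizingError):
            pt.make_genome(plan)

    @pytest.mark.parametrize(
        "field,value",
        [("nb_dispersion", 0.0), ("within_block_r2", 1.2),
         ("frac_peaks_in_enhancers", -0.1), ("n_samples", -1)],
    )
    def test_invalid_plan_rejected(self, field, value):
        with pytest.raises(PlanError):
            pt.SimulationPlan(**{field: value})

    def test_yaml_round_trip(self, tmp_path):
        plan = pt.SimulationPlan(n_snps=500, within_block_r2=0.85,
                                 condition_log2fc_effects={"G0001": 2.0})
        p = tmp_path / "plan.yaml"
        plan.to_yaml(p)
        assert pt.SimulationPlan.from_yaml(p) == plan


class TestSimulatePanel:
    def test_perfect_ld_duplicates_columns(self):
        plan = pt.SimulationPlan(chrom_lengths=(2_000_000,), n_snps=50,
                                 snps_per_block=5, within_block_r2=1.0,
                                 peak_count=0, enhancer_count=0,
                                 n_causal_in_peaks=0, n_causal_outside=0)
        genome = pt.make_genome(plan)
        panel = pt.simulate_panel(plan, genome, np.random.default_rng(0))
        for b in np.unique(panel.block_ids):
            cols = np.flatnonzero(panel.block_ids == b)
            for j in cols[1:]:
                assert np.array_equal(panel.dosages[:, cols[0]],
                                      panel.dosages[:, j])
                assert pt.compute_r2(panel, str(panel.snp_ids[cols[0]]),
                                     str(panel.snp_ids[j])) == 1.0

    def test_within_block_r2_near_target(self):
        plan = pt.SimulationPlan(chrom_lengths=(5_000_000,), n_snps=400,
                                 snps_per_block=8, within_block_r2=0.8,
                                 n_samples=400, peak_count=0,
                                 enhancer_count=0, n_causal_in_peaks=0,
                                 n_causal_outside=0)
        genome = pt.make_genome(plan)
        panel = pt.simulate_panel(plan, genome, np.random.default_rng(1))
        r2s = []
        for b in np.unique(panel.block_ids)[:25]:
            cols = np.flatnonzero(panel.block_ids == b)
            r2s.append(pt.compute_r2(panel, str(panel.snp_ids[cols[0]]),
                                     str(panel.snp_ids[cols[1]])))
        assert abs(np.mean(r2s) - 0.8) < 0.1

    def test_across_block_r2_matches_independence(self):
        """For independent dosage vectors E[r^2] ~ 1/(n_samples - 1)."""
        plan = pt.SimulationPlan(chrom_lengths=(5_000_000,), n_snps=200,
                                 snps_per_block=2, n_samples=500,
                                 peak_count=0, enhancer_count=0,
                                 n_causal_in_peaks=0, n_causal_outside=0)
        genome = pt.make_genome(plan)
        panel = pt.simulate_panel(plan, genome, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        r2s = []
        blocks = panel.block_ids
        while len(r2s) < 100:
            i, j = rng.integers(0, panel.n_snps, 2)
            if blocks[i] != blocks[j]:
                r2s.append(pt.compute_r2(panel, str(panel.snp_ids[i]),
                                         str(panel.snp_ids[j])))
        expected = 1 / (plan.n_samples - 1)
        assert abs(np.mean(r2s) - expected) < 4 * expected

    def test_no_monomorphic_snps(self):
        plan = pt.SimulationPlan(chrom_lengths=(3_000_000,), n_snps=300,
                                 snps_per_block=6, maf_range=(0.05, 0.5),
                                 peak_count=0, enhancer_count=0,
                                 n_causal_in_peaks=0, n_causal_outside=0)
        genome = pt.make_genome(plan)
        panel = pt.simulate_panel(plan, genome, np.random.default_rng(4))
        assert (panel.dosages.max(axis=0) > panel.dosages.min(axis=0)).all()

    def test_dosages_valid(self, small_bundle):
        d = small_bundle["panel"].dosages
        assert set(np.unique(d)) <= {0, 1, 2}


class TestSimulateGwas:
    def _setup(self, **kw):
        plan = pt.SimulationPlan(
            chrom_lengths=(4_000_000, 4_000_000), n_snps=800,
            snps_per_block=8, peak_count=30, enhancer_count=60, **kw
        )
        genome = pt.make_genome(plan)
        rng = np.random.default_rng(5)
        panel = pt.simulate_panel(plan, genome, rng)
        peaks, enh = pt.simulate_features(plan, genome, panel, rng)
        return plan, genome, panel, peaks, rng

    def test_null_plan_has_no_genomewide_hits(self):
        plan, genome, panel, peaks, rng = self._setup(
            n_causal_in_peaks=0, n_causal_outside=0
        )
        stats, truth = pt.simulate_gwas(plan, genome, panel, peaks, rng)
        # expected chance count = n_snps * 5e-8 ~ 4e-5
        assert (stats.df["pvalue"] <= 5e-8).sum() == 0
        assert truth.empty

    def test_pvalues_in_unit_interval(self):
        plan, genome, panel, peaks, rng = self._setup(
            n_causal_in_peaks=3, n_causal_outside=3
        )
        stats, _ = pt.simulate_gwas(plan, genome, panel, peaks, rng)
        p = stats.df["pvalue"]
        assert ((p > 0) & (p <= 1)).all()

    def test_planted_loci_recovered_by_clumping(self):
        """Four in-peak causal loci on the plan -> clumping finds >= 4 loci
        overlapping peaks."""
        plan, genome, panel, peaks, rng = self._setup(
            n_causal_in_peaks=4, n_causal_outside=0
        )
        stats, truth = pt.simulate_gwas(plan, genome, panel, peaks, rng)
        loci = pt.clump(stats, panel)
        assert pt.count_locus_overlaps(loci, peaks) >= 4
        assert set(truth["index_snp"]) <= {l.index_snp for l in loci}

    def test_requesting_too_many_causal_errors(self):
        plan, genome, panel, peaks, rng = self._setup(
            n_causal_in_peaks=0, n_causal_outside=0
        )
        import dataclasses
        bad = dataclasses.replace(plan, n_causal_in_peaks=500)
        with pytest.raises(SizingError):
            pt.simulate_gwas(bad, genome, panel, peaks, rng)


class TestSimulateCounts:
    def test_null_effects_equal_group_means(self):
        plan = pt.SimulationPlan(nb_dispersion=0.05)
        cond = np.array([0] * 50 + [1] * 50)
        counts, truth = pt.simulate_counts(
            plan, 60, cond, rng=np.random.default_rng(6)
        )
        m = counts.to_numpy(dtype=float)
        ratio = np.log2(m[:, cond == 1].mean(axis=1)
                        / m[:, cond == 0].mean(axis=1))
        assert abs(ratio.mean()) < 0.05
        assert (truth["condition_log2fc"] == 0).all()

    def test_planted_log2fc_recovered(self):
        plan = pt.SimulationPlan(
            nb_dispersion=0.05,
            condition_log2fc_effects={"G0001": 2.0},
        )
        cond = np.array([0] * 10 + [1] * 10)
        counts, _ = pt.simulate_counts(
            plan, 30, cond, rng=np.random.default_rng(7)
        )
        row = counts.loc["G0001"].to_numpy(dtype=float)
        est = np.log2(row[cond == 1].mean() / row[cond == 0].mean())
        assert abs(est - 2.0) < 0.3

    def test_small_dispersion_poisson_limit(self):
        plan = pt.SimulationPlan(nb_dispersion=1e-4,
                                 nb_mean_range=(200.0, 200.0))
        counts, _ = pt.simulate_counts(
            plan, 300, np.zeros(200), rng=np.random.default_rng(8)
        )
        m = counts.to_numpy(dtype=float)
        ratio = m.var(axis=1, ddof=1) / m.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1


class TestDatasetBundle:
    def test_same_seed_byte_identical(self, small_plan, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        pt.write_dataset(small_plan, a, seed=3)
        pt.write_dataset(small_plan, b, seed=3)
        files = sorted(p.name for p in a.iterdir())
        assert files == sorted(p.name for p in b.iterdir())
        for name in files:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_outputs_round_trip_through_readers(self, small_bundle):
        paths = small_bundle["paths"]
        stats = pt.SummaryStats.read_tsv(paths["stats"])
        assert len(stats) == small_bundle["panel"].n_snps

        dosage = pt.GenotypePanel.from_dosage_tsv(paths["panel_dosage"])
        vcf = pt.GenotypePanel.from_vcf(paths["panel_vcf"])
        assert np.array_equal(dosage.dosages, small_bundle["panel"].dosages)
        # VCF is position-sorted; compare per SNP id
        for sid in dosage.snp_ids[:50]:
            assert np.array_equal(vcf.column(str(sid)), dosage.column(str(sid)))

        peaks = pt.RegionSet.read_bed(paths["peaks_true"])
        assert len(peaks) == len(small_bundle["peaks"])
        genome = pt.GenomeLayout.from_tsv(paths["genome"])
        assert genome == small_bundle["genome"]

    def test_consensus_of_replicates_recovers_truth(self, small_bundle):
        cons = pt.consensus_peaks(small_bundle["peak_sets"], 2)
        truth = small_bundle["peaks"]
        assert len(cons) == len(truth)
        # each consensus peak covers its true peak's centre
        for r in truth:
            centre = (r.start + r.end) // 2
            assert cons.positions_in(r.chrom, np.array([centre]))[0]

    def test_replicates_need_two_datasets(self, small_plan, small_bundle):
        import dataclasses
        bad = dataclasses.replace(small_plan, n_peak_datasets=1)
        with pytest.raises(PlanError):
            replicate_peak_sets(bad, small_bundle["peaks"],
                                small_bundle["genome"])
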