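"""Shuffling null models and empirical p-values."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pathtune as pt
from pathtune.errors import ConfigError, PlacementError

from conftest import make_locus


def regionset(rows, label=""):
    return pt.RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), label=label
    )


GENOME = pt.GenomeLayout(("chr1", "chr2"), (1_000_000, 500_000))


class TestShuffleBlocks:
    def test_lengths_and_offsets_conserved(self):
        loci = [make_locus("chr1", [100, 250, 900], name="a"),
                make_locus("chr2", [5], name="b")]
        cfg = pt.ShuffleConfig(n_iter=1)
        out = pt.shuffle_blocks(loci, GENOME, cfg, np.random.default_rng(0))
        for old, new in zip(loci, out):
            assert new.span_length == old.span_length
            assert list(new.member_offsets) == list(old.member_offsets)
            assert new.chrom in GENOME.chrom_names

    def test_same_seed_identical(self):
        loci = [make_locus("chr1", [100, 300])]
        cfg = pt.ShuffleConfig(n_iter=1)
        a = pt.shuffle_blocks(loci, GENOME, cfg, np.random.default_rng(42))
        b = pt.shuffle_blocks(loci, GENOME, cfg, np.random.default_rng(42))
        assert a == b

    def test_start_uniform_on_single_chromosome(self):
        """1-bp block on one chromosome: placement passes a chi-square
        uniformity check over 10^5 draws."""
        genome = pt.GenomeLayout(("chr1",), (50,))
        locus = make_locus("chr1", [0])
        cfg = pt.ShuffleConfig(n_iter=1)
        rng = np.random.default_rng(123)
        batch = [locus] * 100  # blocks are placed independently
        draws = np.array([
            placed.member_pos[0]
            for _ in range(1_000)
            for placed in pt.shuffle_blocks(batch, genome, cfg, rng)
        ])
        counts = np.bincount(draws, minlength=50)
        chi2 = ((counts - 2000.0) ** 2 / 2000.0).sum()
        assert sps.chi2.sf(chi2, 49) > 0.01

    def test_block_longer_than_every_chromosome_errors(self):
        locus = make_locus("chr1", [0, 2_000_000])
        with pytest.raises(PlacementError):
            pt.shuffle_blocks([locus], GENOME, pt.ShuffleConfig(n_iter=1),
                              np.random.default_rng(0))


class TestShufflePeaksWithin:
    def test_forced_placement(self):
        peaks = regionset([("chr1", 100, 200)])
        background = regionset([("chr2", 5000, 5100)])
        out = pt.shuffle_peaks_within(
            peaks, background, pt.ShuffleConfig(n_iter=1),
            np.random.default_rng(0),
        )
        assert [(r.chrom, r.start, r.end) for r in out] == \
            [("chr2", 5000, 5100)]

    def test_length_multiset_preserved(self):
        rng = np.random.default_rng(1)
        peaks = regionset(
            [("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 10_000, 10),
                             rng.integers(10, 200, 10))]
        )
        background = regionset([("chr1", 0, 100_000), ("chr2", 0, 50_000)])
        out = pt.shuffle_peaks_within(
            peaks, background, pt.ShuffleConfig(n_iter=1), rng
        )
        assert sorted(r.length for r in out) == sorted(r.length for r in peaks)
        # containment in the background
        for r in out:
            assert background.interval_intersects(r.chrom, r.start, r.end)

    def test_destination_split_between_equal_regions(self):
        peaks = regionset([("chr1", 0, 100)])
        background = regionset([("chr1", 0, 10_000), ("chr2", 0, 10_000)])
        rng = np.random.default_rng(7)
        cfg = pt.ShuffleConfig(n_iter=1)
        batch = regionset([("chr1", 0, 100)] * 50)  # placed independently
        n = 10_000
        hits = sum(
            int((pt.shuffle_peaks_within(batch, background, cfg, rng)
                 .df["chrom"] == "chr1").sum())
            for _ in range(n // 50)
        )
        assert sps.binomtest(hits, n, 0.5).pvalue > 1e-4

    def test_peak_fits_nowhere_errors(self):
        peaks = regionset([("chr1", 0, 5000)])
        background = regionset([("chr1", 0, 100)])
        with pytest.raises(PlacementError):
            pt.shuffle_peaks_within(peaks, background,
                                    pt.ShuffleConfig(n_iter=1),
                                    np.random.default_rng(0))


class TestPermutationTest:
    def test_saturated_overlap_p_one(self):
        genome = pt.GenomeLayout(("chr1",), (10_000,))
        peaks = regionset([("chr1", 0, 10_000)])
        loci = [make_locus("chr1", [5], name=f"l{i}") for i in range(3)]
        cfg = pt.ShuffleConfig(n_iter=200, seed=0)
        res = pt.locus_shuffle_test(loci, peaks, genome, cfg)
        assert res.observed == 3
        assert res.p_empirical == 1.0
        assert np.all(res.null_counts == 3)

    def test_analytic_coverage_probability(self):
        """1-bp locus, peaks covering 10% of a gap-free genome: the null
        overlap is Bernoulli(~0.1)."""
        genome = pt.GenomeLayout(("chr1",), (100_000,))
        peaks = regionset([("chr1", i * 10_000, i * 10_000 + 1_000)
                           for i in range(10)])
        locus = make_locus("chr1", [50])
        cfg = pt.ShuffleConfig(n_iter=10_000, seed=3)
        res = pt.locus_shuffle_test([locus], peaks, genome, cfg)
        se = np.sqrt(0.1 * 0.9 / cfg.n_iter)
        assert abs(res.null_mean - 0.1) < 3 * se

    def test_observed_above_all_null_reported_as_bound(self):
        genome = pt.GenomeLayout(("chr1",), (1_000_000,))
        peaks = regionset([("chr1", 0, 10)])
        locus = make_locus("chr1", [5])
        cfg = pt.ShuffleConfig(n_iter=1_000, seed=1)
        res = pt.locus_shuffle_test([locus], peaks, genome, cfg)
        assert res.observed == 1
        assert res.p_is_bound
        assert res.p_empirical == 0.0
        assert res.p_text() == "p < 0.001"

    def test_reproducible_for_fixed_seed(self):
        genome = pt.GenomeLayout(("chr1", "chr2"), (200_000, 100_000))
        rng = np.random.default_rng(5)
        loci = [make_locus("chr1", sorted(rng.integers(0, 190_000, 3)),
                           name=f"l{i}") for i in range(8)]
        peaks = regionset(
            [("chr1", int(s), int(s) + 500)
             for s in rng.integers(0, 190_000, 30)]
        )
        cfg = pt.ShuffleConfig(n_iter=5_000, seed=99)
        a = pt.locus_shuffle_test(loci, peaks, genome, cfg)
        b = pt.locus_shuffle_test(loci, peaks, genome, cfg)
        assert a.p_empirical == b.p_empirical
        assert np.array_equal(a.null_counts, b.null_counts)

    def test_generic_route_agrees_with_vectorised_route(self):
        """The generic shuffle+count loop and the vectorised test estimate
        the same null (independent RNG streams, so agreement is statistical)."""
        genome = pt.GenomeLayout(("chr1",), (100_000,))
        rng = np.random.default_rng(11)
        loci = [make_locus("chr1", sorted(rng.integers(0, 90_000, 2)),
                           name=f"l{i}") for i in range(6)]
        peaks = regionset(
            [("chr1", int(s), int(s) + 2_000)
             for s in range(0, 100_000, 10_000)]
        )
        cfg = pt.ShuffleConfig(n_iter=3_000, seed=4)
        fast = pt.locus_shuffle_test(loci, peaks, genome, cfg)
        observed = pt.count_locus_overlaps(loci, peaks)
        shuffle_rng = np.random.default_rng(4)
        generic = pt.permutation_test(
            observed,
            lambda shuffled: pt.count_locus_overlaps(shuffled, peaks),
            lambda _rng: pt.shuffle_blocks(loci, genome, cfg, shuffle_rng),
            cfg,
        )
        assert generic.observed == fast.observed
        assert abs(generic.null_mean - fast.null_mean) < 0.15

    def test_n_iter_zero_rejected(self):
        with pytest.raises(ConfigError):
            pt.ShuffleConfig(n_iter=0)

    def test_converse_counts_peaks_not_loci(self):
        genome_bg = regionset([("chr1", 0, 100_000)])
        # two peaks both containing member SNPs of one locus
        peaks = regionset([("chr1", 40, 60), ("chr1", 140, 160)])
        locus = make_locus("chr1", [50, 150])
        cfg = pt.ShuffleConfig(n_iter=500, seed=2)
        res = pt.peak_shuffle_test([locus], peaks, genome_bg, cfg)
        assert res.observed == 2
        assert res.mode == "peak-wise"


class TestMidPAndAddOne:
    def test_add_one_never_zero(self):
        genome = pt.GenomeLayout(("chr1",), (1_000_000,))
        peaks = regionset([("chr1", 0, 10)])
        locus = make_locus("chr1", [5])
        cfg = pt.ShuffleConfig(n_iter=100, seed=1, add_one=True)
        res = pt.locus_shuffle_test([locus], peaks, genome, cfg)
        assert res.p_empirical == pytest.approx(1 / 101)
        assert not res.p_is_bound

    def test_mid_p_halves_tie_weight(self):
        genome = pt.GenomeLayout(("chr1",), (10_000,))
        peaks = regionset([("chr1", 0, 10_000)])
        locus = make_locus("chr1", [5])
        res_up = pt.locus_shuffle_test(
            [locus], peaks, genome, pt.ShuffleConfig(n_iter=100, seed=0)
        )
        res_mid = pt.locus_shuffle_test(
            [locus], peaks, genome,
            pt.ShuffleConfig(n_iter=100, seed=0, tail="mid"),
        )
        assert res_up.p_empirical == 1.0  # all null counts tie the observed
        assert res_mid.p_empirical == pytest.approx(0.5)
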