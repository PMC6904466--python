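"""Interval algebra: consensus peaks, overlap/proximity counting, gene
assignment, BED round-trips."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathtune as pt
from pathtune.errors import ConfigError

from conftest import make_locus
from oracles import (allpairs_consensus, allpairs_locus_overlap,
                     allpairs_peak_overlap)


def regionset(rows, label=""):
    return pt.RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), label=label
    )


class TestConsensusPeaks:
    def test_identical_peak_in_two_of_two(self):
        a = regionset([("chr1", 100, 200)], "ds1")
        b = regionset([("chr1", 100, 200)], "ds2")
        cons = pt.consensus_peaks([a, b])
        assert [(r.chrom, r.start, r.end) for r in cons] == [("chr1", 100, 200)]

    def test_unsupported_peak_dropped(self):
        sets = [regionset([], f"ds{i}") for i in range(4)]
        sets.append(regionset([("chr1", 0, 100)], "ds5"))
        assert len(pt.consensus_peaks(sets)) == 0

    def test_single_linkage_union_span(self):
        a = regionset([("chr1", 0, 100)], "ds1")
        b = regionset([("chr1", 90, 200)], "ds2")
        cons = pt.consensus_peaks([a, b])
        assert [(r.chrom, r.start, r.end) for r in cons] == [("chr1", 0, 200)]

    def test_bookended_peaks_do_not_cluster(self):
        a = regionset([("chr1", 0, 100)], "ds1")
        b = regionset([("chr1", 100, 200)], "ds2")
        assert len(pt.consensus_peaks([a, b])) == 0

    def test_min_datasets_above_set_count_errors(self):
        with pytest.raises(ConfigError):
            pt.consensus_peaks([regionset([("chr1", 0, 10)], "ds1")], 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_allpairs_union_find(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        sets = []
        for ds in range(4):
            sub = []
            for _ in range(rng.integers(5, 25)):
                chrom = f"chr{rng.integers(1, 3)}"
                s = int(rng.integers(0, 5000))
                e = s + int(rng.integers(1, 400))
                sub.append((chrom, s, e))
                rows.append((chrom, s, e, f"ds{ds}"))
            sets.append(regionset(sub, f"ds{ds}"))
        for min_ds in (2, 3):
            got = sorted(
                (r.chrom, r.start, r.end) for r in pt.consensus_peaks(sets, min_ds)
            )
            assert got == allpairs_consensus(rows, min_ds)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(9)
        sets = []
        for ds in range(3):
            rows = [
                ("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 3000, 15),
                                rng.integers(1, 300, 15))
            ]
            sets.append(regionset(rows, f"ds{ds}"))
        a = pt.consensus_peaks(sets)
        b = pt.consensus_peaks(sets[::-1])
        assert [(r.chrom, r.start, r.end) for r in a] == \
            [(r.chrom, r.start, r.end) for r in b]


class TestCounting:
    def test_empty_peaks_zero(self):
        loci = [make_locus("chr1", [100])]
        assert pt.count_locus_overlaps(loci, regionset([])) == 0

    def test_half_open_boundary(self):
        locus = make_locus("chr1", [100])
        hit = regionset([("chr1", 100, 110)])
        miss = regionset([("chr1", 90, 100)])
        assert pt.count_locus_overlaps([locus], hit) == 1
        assert pt.count_locus_overlaps([locus], miss) == 0

    def test_locus_counts_once_despite_two_peaks(self):
        locus = make_locus("chr1", [100, 200])
        peaks = regionset([("chr1", 90, 110), ("chr1", 190, 210)])
        assert pt.count_locus_overlaps([locus], peaks) == 1
        assert pt.count_peak_overlaps([locus], peaks) == 2

    def test_two_loci_one_peak_counts_one_peak(self):
        loci = [make_locus("chr1", [100], name="a"),
                make_locus("chr1", [150], name="b")]
        peaks = regionset([("chr1", 50, 200)])
        assert pt.count_peak_overlaps(loci, peaks) == 1
        assert pt.count_locus_overlaps(loci, peaks) == 2

    def test_disjoint_zero(self):
        loci = [make_locus("chr1", [100])]
        peaks = regionset([("chr2", 90, 110)])
        assert pt.count_peak_overlaps(loci, peaks) == 0

    def test_window_zero_equals_direct_overlap(self):
        rng = np.random.default_rng(2)
        loci = [
            make_locus("chr1", sorted(rng.choice(10_000, 3, replace=False)),
                       name=f"l{i}")
            for i in range(10)
        ]
        peaks = regionset(
            [("chr1", int(s), int(s) + 50) for s in rng.integers(0, 10_000, 20)]
        )
        assert pt.count_proximal(loci, peaks, window=0) == \
            pt.count_locus_overlaps(loci, peaks)

    def test_proximity_inclusive_at_window(self):
        # peak covers [200, 210); SNP at 209 + 25000 is exactly 25 kb from
        # the last covered base and must count; one bp further must not
        locus_at = make_locus("chr1", [209 + 25_000])
        locus_past = make_locus("chr1", [210 + 25_000])
        peaks = regionset([("chr1", 200, 210)])
        assert pt.count_proximal([locus_at], peaks, 25_000) == 1
        assert pt.count_proximal([locus_past], peaks, 25_000) == 0

    @pytest.mark.parametrize("mode", ["snp", "span"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_allpairs_scan(self, seed, mode):
        rng = np.random.default_rng(seed)
        loci = [
            make_locus(
                f"chr{rng.integers(1, 3)}",
                sorted(rng.choice(50_000, rng.integers(1, 6), replace=False)),
                name=f"l{i}",
            )
            for i in range(15)
        ]
        rows = [
            (f"chr{rng.integers(1, 3)}", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 50_000, 40),
                            rng.integers(1, 2_000, 40))
        ]
        peaks = regionset(rows)
        for window in (0, 500, 5_000):
            got = pt.count_proximal(loci, peaks, window, mode=mode)
            assert got == allpairs_locus_overlap(loci, rows, mode, window)
        if mode == "snp":
            assert pt.count_peak_overlaps(loci, peaks) == \
                allpairs_peak_overlap(loci, rows)

    @given(st.integers(0, 30_000), st.integers(0, 30_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_proximal_monotone_in_window(self, w1, w2):
        rng = np.random.default_rng(5)
        loci = [make_locus("chr1", [int(p)], name=f"l{i}")
                for i, p in enumerate(rng.integers(0, 100_000, 12))]
        peaks = regionset(
            [("chr1", int(s), int(s) + 100)
             for s in rng.integers(0, 100_000, 15)]
        )
        lo, hi = sorted((w1, w2))
        assert pt.count_proximal(loci, peaks, lo) <= \
            pt.count_proximal(loci, peaks, hi)


class TestAssignGenes:
    def setup_method(self):
        self.locus = make_locus("chr1", [100_000, 101_000])

    def test_distant_gene_without_interaction_excluded(self):
        gene = pt.GeneModel("G1", "chr1", 131_000, 150_000, "+", 131_000)
        assert pt.assign_genes(self.locus, [gene]) == set()

    def test_distant_gene_with_interaction_included(self):
        gene = pt.GeneModel("G1", "chr1", 131_000, 150_000, "+", 131_000)
        it = pt.InteractionTable([
            pt.Interaction(
                target=pt.Region("chr1", 131_500, 133_000),  # TSS + 1 kb in
                viewpoint=pt.Region("chr1", 100_000, 101_001),
            )
        ])
        assert pt.assign_genes(self.locus, [gene], it) == {"G1"}

    def test_promoter_window_inclusive(self):
        # target touching exactly TSS + 2 kb is still a promoter contact
        gene = pt.GeneModel("G1", "chr1", 200_000, 220_000, "+", 200_000)
        it = pt.InteractionTable([
            pt.Interaction(target=pt.Region("chr1", 202_000, 202_500),
                           locus_id="L")
        ])
        assert pt.assign_genes(self.locus, [gene], it) == {"G1"}

    def test_nearby_gene_included(self):
        gene = pt.GeneModel("G1", "chr1", 120_000, 140_000, "+", 120_000)
        assert pt.assign_genes(self.locus, [gene]) == {"G1"}

    def test_empty_inputs(self):
        assert pt.assign_genes(self.locus, [], pt.InteractionTable()) == set()


class TestIO:
    def test_bed_round_trip(self, tmp_path):
        rs = regionset(
            [("chr2", 5, 50), ("chr1", 0, 10), ("chr1", 20, 30)], "x"
        )
        p = tmp_path / "t.bed"
        rs.to_bed(p)
        back = pt.RegionSet.read_bed(p)
        assert [(r.chrom, r.start, r.end) for r in back] == \
            [(r.chrom, r.start, r.end) for r in rs]

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            pt.Region("chr1", 10, 10)
        with pytest.raises(ValueError):
            regionset([("chr1", 50, 40)])

    def test_interaction_table_round_trip(self, tmp_path):
        it = pt.InteractionTable([
            pt.Interaction(target=pt.Region("chr2", 10, 20),
                           viewpoint=pt.Region("chr1", 0, 5), locus_id="L1"),
            pt.Interaction(target=pt.Region("chr3", 7, 9)),
        ])
        p = tmp_path / "i.tsv"
        it.to_tsv(p)
        back = pt.InteractionTable.read_tsv(p)
        assert len(back) == 2
        assert back.interactions[0].locus_id == "L1"
        assert back.interactions[0].target == pt.Region("chr2", 10, 20)
        assert back.interactions[1].viewpoint is None
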