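"""The 13 published renal-cell-carcinoma susceptibility loci as a fixture.

Each row records a locus name, its index SNP and p-value, its published
proximity to a HIF-binding site (direct overlap, within 25 kb, or none),
whether a long-range chromatin interaction with a binding site was reported,
and the regulation call for each proximal/interacting protein-coding gene
(up / down / flat / not-expressed under VHL loss).

``realize`` lays the rows out in a synthetic coordinate space (one
chromosome per locus) whose geometry reproduces the published counting:
4 loci directly overlap a binding site, one of them overlaps two distinct
sites (5 sites hit in total), and 7 loci overlap or lie within 25 kb of a
site. The regulation arrows are carried as labels only; the specific genes
are not simulated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout
from .intervals import (GeneModel, Interaction, InteractionTable, Region,
                        RegionSet)
from .ldloci import RiskLocus

__all__ = ["Table1Row", "Table1Fixture", "table1_fixture"]

PROXIMITIES = {"overlap", "within-25kb", "none"}
REGULATION = {"up", "down", "flat", "ne"}


@dataclass(frozen=True)
class Table1Row:
    locus: str
    index_snp: str
    pvalue: float
    proximity: str  # overlap | within-25kb | none
    interaction: bool
    genes: tuple[tuple[str, str], ...]  # (gene, regulation label)

    def __post_init__(self) -> None:
        if self.pvalue <= 0:
            raise ValueError("p-value must be positive")
        if self.proximity not in PROXIMITIES:
            raise ValueError(f"unknown proximity label {self.proximity!r}")
        for _, reg in self.genes:
            if reg not in REGULATION:
                raise ValueError(f"unknown regulation label {reg!r}")


_ROWS = [
    ("11q13.3", "rs11263654", 1.65e-23, "overlap", False,
     (("CCND1", "up"), ("MYEOV", "ne"), ("ORAOV1", "up"))),
    ("2p21", "rs2121267", 6.95e-19, "none", True,
     (("EPAS1", "down"),)),
    ("12p12.1", "rs11534749", 6.19e-17, "overlap", False,
     (("BHLHE41", "flat"), ("ITPR2", "up"), ("SSPN", "ne"))),
    ("14q24.2", "rs28840762", 1.08e-15, "none", False,
     (("DPF3", "ne"),)),
    ("12q24.31", "rs10846748", 1.70e-12, "within-25kb", False,
     (("SCARB1", "up"),)),
    ("8q24.21", "rs6470588", 2.82e-12, "overlap", False,
     (("MYC", "up"),)),
    ("11q22.3", "rs117706999", 6.60e-10, "none", False,
     (("DDX10", "up"), ("EXPH5", "ne"), ("ATM", "up"), ("NPAT", "flat"),
      ("C11orf65", "ne"), ("KDELC2", "down"))),
    ("2q22.3", "rs11888238", 8.15e-10, "none", False,
     (("ZEB2", "up"),)),
    ("1p32.3", "rs6676515", 3.04e-09, "none", False,
     (("FAF1", "flat"), ("DMRTA2", "ne"))),
    ("4q23", "rs7697932", 4.70e-09, "within-25kb", False, ()),
    ("3p22.1", "rs9821249", 1.12e-08, "none", False,
     (("EIF1B", "down"), ("ENTPD3", "ne"), ("RPL14", "down"),
      ("ZNF619", "up"), ("ZNF620", "ne"), ("ZNF621", "up"))),
    ("15q22.31", "rs12905354", 2.28e-08, "within-25kb", False,
     (("DIS3L", "flat"), ("MAP2K1", "up"), ("MEGF11", "ne"),
      ("SMAD6", "flat"), ("SNAPC5", "down"), ("TIPIN", "up"),
      ("ZWILCH", "up"), ("RPL4", "flat"))),
    ("3q26.31", "rs234043", 4.10e-08, "overlap", False,
     (("ECT2", "up"), ("TNFSF10", "up"))),
]

# Which overlapping locus hits two distinct binding sites is not identified
# in print; the realization assigns the double hit to 11q13.3 (synthetic
# choice, affects only geometry, not the counts).
_DOUBLE_HIT_LOCUS = "11q13.3"

_CHROM_LEN = 2_000_000
_INDEX_POS = 1_000_000
_BLOCK_HALF = 10_000  # member SNPs at index +/- 10 kb
_NEAR_GAP = 10_000  # gap used for "within-25kb" rows
_FAR_GAP = 200_000  # gap used for "none" rows that still get a distal site


class Table1Fixture:
    """The printed locus table plus a synthetic geometric realization."""

    def __init__(self, rows: list[Table1Row]):
        self.rows = rows
        names = [r.locus for r in rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus rows")

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, locus: str) -> Table1Row:
        for r in self.rows:
            if r.locus == locus:
                return r
        raise KeyError(locus)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus": r.locus,
                    "index_snp": r.index_snp,
                    "pvalue": r.pvalue,
                    "proximity": r.proximity,
                    "interaction": r.interaction,
                    "genes": ",".join(f"{g}:{reg}" for g, reg in r.genes),
                }
                for r in self.rows
            ]
        )

    @property
    def gene_labels(self) -> dict[str, str]:
        out = {}
        for r in self.rows:
            out.update(dict(r.genes))
        return out

    # -- geometric realization --------------------------------------------
    def realize(self) -> dict:
        """Deterministic synthetic coordinates reproducing the published
        counting. One 2-Mb chromosome per locus; the index SNP sits at 1 Mb
        with two flanking block members at +/- 10 kb.

        Returns a dict with ``genome``, ``loci``, ``peaks``, ``genes``,
        ``interactions``.
        """
        chrom_names, loci, peak_rows, genes, interactions = [], [], [], [], []
        for r in self.rows:
            chrom = f"chr{r.locus}"
            chrom_names.append(chrom)
            member_pos = (
                _INDEX_POS - _BLOCK_HALF, _INDEX_POS, _INDEX_POS + _BLOCK_HALF
            )
            member_ids = (
                f"{r.index_snp}_l", r.index_snp, f"{r.index_snp}_r"
            )
            loci.append(
                RiskLocus(
                    name=r.locus, chrom=chrom, index_snp=r.index_snp,
                    index_pos=_INDEX_POS, index_pvalue=r.pvalue,
                    member_ids=member_ids, member_pos=member_pos,
                )
            )
            if r.proximity == "overlap":
                # site covering the index SNP
                peak_rows.append(
                    (chrom, _INDEX_POS - 300, _INDEX_POS + 300,
                     f"site_{r.locus}")
                )
                if r.locus == _DOUBLE_HIT_LOCUS:
                    # second distinct site covering a flanking member SNP
                    p = _INDEX_POS + _BLOCK_HALF
                    peak_rows.append(
                        (chrom, p - 300, p + 300, f"site_{r.locus}_b")
                    )
            elif r.proximity == "within-25kb":
                # site whose nearest base sits _NEAR_GAP bp from the
                # rightmost member SNP
                s = _INDEX_POS + _BLOCK_HALF + _NEAR_GAP
                peak_rows.append((chrom, s, s + 600, f"site_{r.locus}"))
            elif r.interaction:
                # distal site, well beyond the 25-kb window, contacted by
                # the locus in the interaction table
                s = _INDEX_POS + _FAR_GAP
                peak_rows.append((chrom, s, s + 600, f"site_{r.locus}"))
                interactions.append(
                    Interaction(
                        target=Region(chrom, s - 2_000, s + 2_600),
                        viewpoint=Region(chrom, _INDEX_POS - _BLOCK_HALF,
                                         _INDEX_POS + _BLOCK_HALF + 1),
                        locus_id=r.locus,
                    )
                )
            # gene models: listed genes placed proximal to the locus, except
            # interaction-only rows whose gene promoter sits at the distal
            # target
            for k, (gene, _reg) in enumerate(r.genes):
                if r.interaction:
                    tss = _INDEX_POS + _FAR_GAP + 300
                else:
                    tss = _INDEX_POS + 15_000 + 2_000 * k
                genes.append(
                    GeneModel(gene, chrom, tss, tss + 20_000, "+", tss)
                )
        genome = GenomeLayout(
            tuple(chrom_names), tuple([_CHROM_LEN] * len(chrom_names))
        )
        peaks = RegionSet(
            pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"]),
            label="binding-sites",
        )
        return {
            "genome": genome,
            "loci": loci,
            "peaks": peaks,
            "genes": genes,
            "interactions": InteractionTable(interactions),
        }


def table1_fixture() -> Table1Fixture:
    """The published locus table, verbatim."""
    return Table1Fixture([Table1Row(*row) for row in _ROWS])
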