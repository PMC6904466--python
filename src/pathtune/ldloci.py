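"""Independent GWAS risk loci from summary statistics and a genotype panel.

A locus is found by iterative clumping: take the most significant remaining
SNP as an index, exclude every SNP in close physical (< ``exclude_dist`` bp)
or genetic (r^2 >= ``exclude_r2``) proximity on the same chromosome, repeat.
Each index then carries its haplotype block: the index plus every panel SNP
with r^2 >= ``block_r2`` (inclusive). Loci are reported in two significance
tiers: supra-threshold (p <= ``p_threshold``) and sub-threshold
(``p_threshold`` < p < ``p_window_low``), the latter only after removing all
SNPs in proximity to any supra-threshold index.

r^2 is the squared Pearson correlation of unphased dosage vectors
(composite LD), as used on dosage data by standard clumping tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, MonomorphicSNPError, SNPLookupError

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "GenotypePanel",
    "ClumpConfig",
    "RiskLocus",
    "compute_r2",
    "clump",
    "define_block",
]

GENOME_WIDE_P = 5e-8


class SummaryStats:
    """Per-SNP association records: chrom, pos (0-based), snp_id, pvalue."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        required = {"chrom", "pos", "snp_id", "pvalue"}
        if not required.issubset(df.columns):
            raise ValueError(f"summary stats need columns {sorted(required)}")
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["snp_id"] = df["snp_id"].astype(str)
        df["pvalue"] = df["pvalue"].astype(float)
        if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in summary stats")
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def pvalue_of(self, snp_id: str) -> float:
        sub = self.df.loc[self.df["snp_id"] == snp_id, "pvalue"]
        if sub.empty:
            raise SNPLookupError(snp_id)
        return float(sub.iloc[0])

    @classmethod
    def read_tsv(cls, path) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False,
                       float_format="%.6g")


class GenotypePanel:
    """Sample x SNP dosage matrix (entries 0/1/2) with a SNP coordinate index.

    Stands in for a phased reference panel; LD is computed on unphased
    dosages.
    """

    def __init__(self, dosages: np.ndarray, snp_ids, chrom, pos,
                 sample_ids=None, block_ids=None):
        dosages = np.asarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        if not np.isin(dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be 0, 1 or 2")
        n_samples, n_snps = dosages.shape
        if not (len(snp_ids) == len(chrom) == len(pos) == n_snps):
            raise ValueError("SNP metadata length mismatch")
        self.dosages = dosages.astype(np.int8)
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.sample_ids = (
            np.asarray(sample_ids, dtype=object)
            if sample_ids is not None
            else np.array([f"S{i + 1}" for i in range(n_samples)], dtype=object)
        )
        self.block_ids = (
            np.asarray(block_ids) if block_ids is not None else None
        )
        self._col = {sid: j for j, sid in enumerate(self.snp_ids)}
        if len(self._col) != n_snps:
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._col

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._col[snp_id]]
        except KeyError:
            raise SNPLookupError(snp_id) from None

    def index_of(self, snp_id: str) -> int:
        try:
            return self._col[snp_id]
        except KeyError:
            raise SNPLookupError(snp_id) from None

    # -- I/O ---------------------------------------------------------------
    def to_dosage_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
        )
        mat = pd.DataFrame(self.dosages.T, columns=self.sample_ids)
        pd.concat([df, mat], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = df[["snp_id", "chrom", "pos"]]
        mat = df.drop(columns=["snp_id", "chrom", "pos"])
        return cls(
            mat.to_numpy().T,
            meta["snp_id"].to_numpy(),
            meta["chrom"].to_numpy(),
            meta["pos"].to_numpy(),
            sample_ids=mat.columns.to_numpy(),
        )

    def to_vcf(self, path, genome=None) -> None:
        """Write a minimal VCF 4.2 with GT fields (REF=A, ALT=G throughout)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if genome is not None:
                for name, length in zip(genome.chrom_names,
                                        genome.chrom_lengths):
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.sample_ids))
                + "\n"
            )
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}
            order = np.lexsort((self.pos, self.chrom.astype(str)))
            for j in order:
                calls = "\t".join(gt[int(d)] for d in self.dosages[:, j])
                fh.write(
                    f"{self.chrom[j]}\t{self.pos[j] + 1}\t{self.snp_ids[j]}"
                    f"\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, poss, cols = [], [], [], []
        for rec in vcf:
            ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            chroms.append(rec.CHROM)
            poss.append(rec.POS - 1)  # VCF is 1-based
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            dos = np.array(
                [{0: 0, 1: 1, 3: 2}[int(t)] for t in rec.gt_types],
                dtype=np.int8,
            )
            cols.append(dos)
        return cls(
            np.column_stack(cols) if cols else np.empty((len(samples), 0)),
            ids, chroms, poss, sample_ids=samples,
        )


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds for locus definition.

    ``exclude_dist`` defaults to 500 kb: large enough to separate
    independent signals, small enough to allow multiple loci per chromosome.
    """

    p_threshold: float = GENOME_WIDE_P
    p_window_low: float = 1e-4
    exclude_dist: int = 500_000
    exclude_r2: float = 0.2
    block_r2: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < self.p_window_low <= 1):
            raise ConfigError("need 0 < p_threshold < p_window_low <= 1")
        if not (0 <= self.exclude_r2 <= self.block_r2 <= 1):
            raise ConfigError("need 0 <= exclude_r2 <= block_r2 <= 1")
        if self.exclude_dist < 0:
            raise ConfigError("exclude_dist must be >= 0")


@dataclass(frozen=True)
class RiskLocus:
    """An index SNP with its haplotype block.

    ``member_pos`` is sorted; ``span`` is the half-open interval covering all
    member SNP bases.
    """

    name: str
    chrom: str
    index_snp: str
    index_pos: int
    index_pvalue: float
    member_ids: tuple[str, ...]
    member_pos: tuple[int, ...]
    tier: str = "supra"

    def __post_init__(self) -> None:
        if self.index_snp not in self.member_ids:
            raise ValueError("index SNP must be a block member")
        if list(self.member_pos) != sorted(self.member_pos):
            raise ValueError("member positions must be sorted")
        if self.tier not in {"supra", "sub"}:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.member_pos[0], self.member_pos[-1] + 1)

    @property
    def span_length(self) -> int:
        return self.member_pos[-1] + 1 - self.member_pos[0]

    @property
    def member_offsets(self) -> np.ndarray:
        return np.asarray(self.member_pos) - self.member_pos[0]


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _r2_vector(panel: GenotypePanel, index_col: int,
               other_cols: np.ndarray) -> np.ndarray:
    """r^2 between one SNP and many, vectorised; monomorphic others get 0."""
    # Dosages are small integers, so every sum below is exact in int64 and
    # r^2 = (n Sxy - Sx Sy)^2 / ((n Sxx - Sx^2)(n Syy - Sy^2)) is computed
    # without square roots: exact cases (copied columns, small panels) give
    # exactly 1.0 or the rational value, keeping threshold tests sharp.
    x = panel.dosages[:, index_col].astype(np.int64)
    y = panel.dosages[:, other_cols].astype(np.int64)
    n = x.shape[0]
    sx, sy = x.sum(), y.sum(axis=0)
    dx = float(n * (x * x).sum() - sx * sx)
    dy = (n * (y * y).sum(axis=0) - sy * sy).astype(float)
    if dx == 0:
        raise MonomorphicSNPError(str(panel.snp_ids[index_col]))
    num = (n * (x @ y) - sx * sy).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (num * num) / (dx * dy)
    r2 = np.where(dy == 0, 0.0, r2)
    return np.clip(r2, 0.0, 1.0)


def compute_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of the two dosage columns."""
    a, b = panel.index_of(snp_a), panel.index_of(snp_b)
    if panel.dosages[:, b].astype(float).var() == 0:
        raise MonomorphicSNPError(snp_b)
    return float(_r2_vector(panel, a, np.array([b]))[0])


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _candidate_frame(stats: SummaryStats, panel: GenotypePanel,
                     lo: float, hi_exclusive: float,
                     inclusive_low: bool) -> pd.DataFrame:
    df = stats.df
    if inclusive_low:
        mask = df["pvalue"] <= lo
    else:
        mask = (df["pvalue"] > lo) & (df["pvalue"] < hi_exclusive)
    cand = df[mask].copy()
    in_panel = cand["snp_id"].isin(panel._col)
    if (~in_panel).any():
        logger.warning(
            "%d candidate SNP(s) absent from the panel were dropped",
            int((~in_panel).sum()),
        )
    cand = cand[in_panel]
    cand["col"] = [panel.index_of(s) for s in cand["snp_id"]]
    return cand


def clump(stats: SummaryStats, panel: GenotypePanel,
          cfg: ClumpConfig | None = None, tier: str = "supra") -> list[RiskLocus]:
    """Iteratively select independent index SNPs and build their blocks.

    Returns loci in increasing p order. For ``tier="sub"`` the supra-threshold
    indices are found first and every sub-threshold candidate in physical or
    LD proximity to any of them is removed before clumping the window
    ``p_threshold < p < p_window_low``.
    """
    cfg = cfg or ClumpConfig()
    if tier == "supra":
        cand = _candidate_frame(stats, panel, cfg.p_threshold, 1.0, True)
    elif tier == "sub":
        cand = _candidate_frame(
            stats, panel, cfg.p_threshold, cfg.p_window_low, False
        )
        supra = clump(stats, panel, cfg, tier="supra")
        for locus in supra:
            cand = _drop_proximal(cand, panel, locus.index_snp, cfg)
    else:
        raise ConfigError(f"unknown tier {tier!r}")

    indices: list[str] = []
    # deterministic priority: smallest p, then chromosome, then position
    cand = cand.sort_values(["pvalue", "chrom", "pos"], kind="mergesort")
    while not cand.empty:
        top = cand.iloc[0]
        indices.append(str(top.snp_id))
        cand = _drop_proximal(cand, panel, str(top.snp_id), cfg)

    return [define_block(idx, stats, panel, cfg, tier=tier) for idx in indices]


def _drop_proximal(cand: pd.DataFrame, panel: GenotypePanel, index_snp: str,
                   cfg: ClumpConfig) -> pd.DataFrame:
    """Remove the index itself and every candidate on its chromosome within
    ``exclude_dist`` bp or with r^2 >= ``exclude_r2``."""
    col = panel.index_of(index_snp)
    chrom = panel.chrom[col]
    pos = panel.pos[col]
    same_chrom = (cand["chrom"] == chrom).to_numpy()
    drop = cand["snp_id"].to_numpy() == index_snp
    near = same_chrom & (np.abs(cand["pos"].to_numpy() - pos) < cfg.exclude_dist)
    drop |= near
    rest = same_chrom & ~drop
    if rest.any():
        cols = cand["col"].to_numpy()[rest]
        try:
            r2 = _r2_vector(panel, col, cols)
        except MonomorphicSNPError:
            logger.warning(
                "index SNP %s is monomorphic in the panel; "
                "LD exclusion skipped for it", index_snp,
            )
            r2 = np.zeros(rest.sum())
        linked = np.zeros(len(cand), dtype=bool)
        linked[np.flatnonzero(rest)] = r2 >= cfg.exclude_r2
        drop |= linked
    return cand[~drop]


def define_block(index: str, stats: SummaryStats, panel: GenotypePanel,
                 cfg: ClumpConfig | None = None,
                 tier: str = "supra") -> RiskLocus:
    """The haplotype block of an index SNP: the index plus every panel SNP on
    the same chromosome with r^2 >= ``block_r2`` (inclusive at the
    threshold)."""
    cfg = cfg or ClumpConfig()
    col = panel.index_of(index)
    chrom = panel.chrom[col]
    same = np.flatnonzero(panel.chrom == chrom)
    try:
        r2 = _r2_vector(panel, col, same)
        linked = same[r2 >= cfg.block_r2]
    except MonomorphicSNPError:
        logger.warning("monomorphic index SNP %s: singleton block", index)
        linked = np.array([col])
    members = np.union1d(linked, [col])
    order = np.argsort(panel.pos[members], kind="mergesort")
    members = members[order]
    try:
        pval = stats.pvalue_of(index)
    except SNPLookupError:
        pval = float("nan")
    return RiskLocus(
        name=index,
        chrom=str(chrom),
        index_snp=index,
        index_pos=int(panel.pos[col]),
        index_pvalue=pval,
        member_ids=tuple(str(s) for s in panel.snp_ids[members]),
        member_pos=tuple(int(p) for p in panel.pos[members]),
        tier=tier,
    )


# ---------------------------------------------------------------------------
# locus I/O
# ---------------------------------------------------------------------------

def loci_to_bed(loci, path) -> None:
    rows = [(l.chrom, l.span[1], l.span[2], l.name, 0, l.tier) for l in loci]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def loci_members_to_tsv(loci, path) -> None:
    rows = []
    for l in loci:
        for sid, pos in zip(l.member_ids, l.member_pos):
            rows.append((l.name, l.tier, l.chrom, sid, pos,
                         int(sid == l.index_snp)))
    pd.DataFrame(
        rows,
        columns=["locus", "tier", "chrom", "snp_id", "pos", "is_index"],
    ).to_csv(path, sep="\t", index=False)
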