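"""Interval algebra on 0-based, half-open genomic regions.

Provides BED I/O, consensus-peak construction across ChIP-seq datasets,
locus/peak overlap and proximity counting, and locus-to-gene assignment.
A SNP at base ``k`` occupies ``[k, k+1)``; all "within W bp" proximity is
measured between covered bases and is inclusive at W.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .errors import ConfigError

__all__ = [
    "Region",
    "RegionSet",
    "GeneModel",
    "Interaction",
    "InteractionTable",
    "consensus_peaks",
    "count_locus_overlaps",
    "count_peak_overlaps",
    "count_proximal",
    "assign_genes",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class RegionSet:
    """A label-tagged collection of regions, position-sorted per chromosome.

    Backed by a pandas DataFrame with columns
    ``chrom, start, end, name, score, source``.
    """

    COLUMNS = ["chrom", "start", "end", "name", "score", "source"]

    def __init__(self, df: pd.DataFrame | None = None, label: str = ""):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df.copy()
        for col, default in (("name", ""), ("score", 0.0), ("source", "")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"invalid region {bad.chrom}:{bad.start}-{bad.end}"
            )
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df.index = np.arange(len(self.df))
        self.label = label
        self._merged_cache: dict[int, dict[str, tuple]] = {}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_regions(cls, regions: Iterable[Region], label: str = "") -> "RegionSet":
        rows = [
            (r.chrom, r.start, r.end, r.name, r.score, r.source)
            for r in regions
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS), label=label)

    @classmethod
    def read_bed(cls, path, label: str = "") -> "RegionSet":
        """Read BED3/BED6 (extra columns beyond 6 are ignored)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, : min(6, df.shape[1])]
        df.columns = cls.COLUMNS[: df.shape[1]]
        return cls(df, label=label or str(path))

    def to_bed(self, path) -> None:
        out = self.df[["chrom", "start", "end"]].copy()
        out["name"] = self.df["name"].replace("", ".")
        out["score"] = self.df["score"]
        out.to_csv(path, sep="\t", header=False, index=False)

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Region]:
        for row in self.df.itertuples(index=False):
            yield Region(row.chrom, int(row.start), int(row.end),
                         str(row.name), float(row.score), str(row.source))

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def total_span(self) -> int:
        """Total covered bases (overlaps counted once)."""
        return sum(
            int((ends - starts).sum())
            for starts, ends in self._merged(0).values()
        )

    # -- queries -----------------------------------------------------------
    def _merged(self, pad: int = 0) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Disjoint sorted intervals per chromosome, optionally padded by
        ``pad`` bp on each side (re-merged after padding; starts clipped at 0)."""
        if pad in self._merged_cache:
            return self._merged_cache[pad]
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            starts = np.maximum(sub["start"].to_numpy() - pad, 0)
            ends = sub["end"].to_numpy() + pad
            order = np.argsort(starts, kind="mergesort")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [], []
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s < cur_e:  # strict: bookended intervals stay separate
                    cur_e = max(cur_e, e)
                else:
                    m_starts.append(cur_s)
                    m_ends.append(cur_e)
                    cur_s, cur_e = s, e
            m_starts.append(cur_s)
            m_ends.append(cur_e)
            out[str(chrom)] = (np.asarray(m_starts), np.asarray(m_ends))
        self._merged_cache[pad] = out
        return out

    def positions_in(self, chrom: str, positions: np.ndarray,
                     pad: int = 0) -> np.ndarray:
        """Boolean mask: which base positions fall inside a (padded) region."""
        positions = np.asarray(positions)
        merged = self._merged(pad)
        if chrom not in merged:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = merged[chrom]
        idx = np.searchsorted(starts, positions, side="right")
        hit = idx > 0
        hit[hit] = positions[hit] < ends[idx[hit] - 1]
        return hit

    def interval_intersects(self, chrom: str, start: int, end: int,
                            pad: int = 0) -> bool:
        """Does ``[start, end)`` intersect any (padded) region?"""
        merged = self._merged(pad)
        if chrom not in merged:
            return False
        starts, ends = merged[chrom]
        j = int(np.searchsorted(ends, start, side="right"))
        return j < len(starts) and starts[j] < end


@dataclass(frozen=True)
class GeneModel:
    """A gene: its genomic span, transcription start site and strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"TSS of {self.gene_id} outside its span")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_genes(path) -> list[GeneModel]:
    """Read a gene table TSV: gene_id, chrom, start, end, strand, tss."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end),
                  r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


def write_genes(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.tss) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand", "tss"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Interaction:
    """One long-range chromatin contact: a viewpoint anchored at a locus and
    the distal target region it touches."""

    target: Region
    viewpoint: Region | None = None
    locus_id: str = ""


class InteractionTable:
    """Locus -> distal-region contacts (stand-in for Capture-C output)."""

    def __init__(self, interactions: Iterable[Interaction] = ()):
        self.interactions = list(interactions)

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self.interactions)

    def for_locus(self, locus) -> list[Interaction]:
        """Contacts anchored at a locus: matched by id, or by the viewpoint
        region overlapping the locus span."""
        chrom, start, end = locus.span
        name = getattr(locus, "name", "")
        out = []
        for it in self.interactions:
            if it.locus_id and name and it.locus_id == name:
                out.append(it)
            elif it.viewpoint is not None and it.viewpoint.overlaps(
                Region(chrom, start, end)
            ):
                out.append(it)
        return out

    # BEDPE-style 7-column TSV
    @classmethod
    def read_tsv(cls, path) -> "InteractionTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        out = []
        for r in df.itertuples(index=False):
            vp = None
            if r.vp_chrom not in ("", ".", None) and not pd.isna(r.vp_chrom):
                vp = Region(r.vp_chrom, int(r.vp_start), int(r.vp_end))
            out.append(
                Interaction(
                    target=Region(r.target_chrom, int(r.target_start),
                                  int(r.target_end)),
                    viewpoint=vp,
                    locus_id="" if pd.isna(r.locus_id) or r.locus_id == "."
                    else str(r.locus_id),
                )
            )
        return cls(out)

    def to_tsv(self, path) -> None:
        rows = []
        for it in self.interactions:
            vp = it.viewpoint
            rows.append(
                (
                    vp.chrom if vp else ".",
                    vp.start if vp else 0,
                    vp.end if vp else 0,
                    it.target.chrom,
                    it.target.start,
                    it.target.end,
                    it.locus_id or ".",
                )
            )
        pd.DataFrame(
            rows,
            columns=["vp_chrom", "vp_start", "vp_end", "target_chrom",
                     "target_start", "target_end", "locus_id"],
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# consensus peaks
# ---------------------------------------------------------------------------

def consensus_peaks(peak_sets: Sequence[RegionSet],
                    min_datasets: int = 2) -> RegionSet:
    """Build consensus binding sites supported by >= ``min_datasets`` datasets.

    Peaks from all input sets are clustered by single-linkage >=1-bp overlap
    (bookended peaks do not cluster); each cluster supported by at least
    ``min_datasets`` distinct datasets is emitted as the union span of its
    members.
    """
    if min_datasets > len(peak_sets):
        raise ConfigError(
            f"min_datasets={min_datasets} exceeds the {len(peak_sets)} "
            "peak sets provided"
        )
    frames = []
    for i, ps in enumerate(peak_sets):
        ds = ps.label or f"dataset_{i}"
        sub = ps.df[["chrom", "start", "end"]].copy()
        sub["dataset"] = ds
        frames.append(sub)
    if len({f["dataset"].iloc[0] for f in frames if len(f)}) < len(
        [f for f in frames if len(f)]
    ):
        raise ConfigError("peak sets must carry distinct dataset labels")
    allpeaks = pd.concat(frames, ignore_index=True)
    if allpeaks.empty:
        return RegionSet(label="consensus")
    gr = pr.PyRanges(
        allpeaks.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
        )
    )
    # slack=-1: require a strictly positive overlap to join a cluster
    clustered = gr.cluster(slack=-1).df
    rows = []
    for cid, grp in clustered.groupby("Cluster"):
        if grp["dataset"].nunique() >= min_datasets:
            rows.append(
                (
                    str(grp["Chromosome"].iloc[0]),
                    int(grp["Start"].min()),
                    int(grp["End"].max()),
                )
            )
    rows.sort()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"consensus_{i + 1}" for i in range(len(df))]
    return RegionSet(df, label="consensus")


# ---------------------------------------------------------------------------
# overlap / proximity counting
# ---------------------------------------------------------------------------

def _locus_hit(locus, peaks: RegionSet, mode: str, pad: int) -> bool:
    chrom, start, end = locus.span
    if mode == "snp":
        pos = np.asarray(locus.member_pos)
        return bool(peaks.positions_in(chrom, pos, pad=pad).any())
    if mode == "span":
        return peaks.interval_intersects(chrom, start, end, pad=pad)
    raise ConfigError(f"unknown overlap mode {mode!r}")


def count_locus_overlaps(loci: Sequence, peaks: RegionSet,
                         mode: str = "snp") -> int:
    """Number of loci with at least one peak hit (each locus counts once,
    however many peaks it touches). In ``snp`` mode a hit is a member SNP
    inside a peak; in ``span`` mode the block span intersecting a peak."""
    return sum(_locus_hit(locus, peaks, mode, pad=0) for locus in loci)


def count_peak_overlaps(loci: Sequence, peaks: RegionSet,
                        mode: str = "snp") -> int:
    """Number of distinct peaks hit by at least one locus (peak-wise)."""
    snp_pos: dict[str, list] = {}
    spans: dict[str, list] = {}
    for locus in loci:
        chrom, start, end = locus.span
        snp_pos.setdefault(chrom, []).extend(np.asarray(locus.member_pos))
        spans.setdefault(chrom, []).append((start, end))
    n = 0
    for row in peaks.df.itertuples(index=False):
        chrom = str(row.chrom)
        if mode == "snp":
            pos = np.sort(np.asarray(snp_pos.get(chrom, [])))
            lo = np.searchsorted(pos, row.start, side="left")
            hi = np.searchsorted(pos, row.end, side="left")
            hit = hi > lo
        elif mode == "span":
            hit = any(s < row.end and row.start < e
                      for s, e in spans.get(chrom, []))
        else:
            raise ConfigError(f"unknown overlap mode {mode!r}")
        n += bool(hit)
    return n


def count_proximal(loci: Sequence, peaks: RegionSet, window: int = 25_000,
                   mode: str = "snp") -> int:
    """Number of loci overlapping or lying within ``window`` bp of a peak.

    Distance is measured between the nearest covered bases and is inclusive
    at ``window``; ``window=0`` reduces to direct overlap.
    """
    if window < 0:
        raise ConfigError("window must be >= 0")
    return sum(_locus_hit(locus, peaks, mode, pad=window) for locus in loci)


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def assign_genes(locus, genes: Sequence[GeneModel],
                 interactions: InteractionTable | None = None,
                 near_window: int = 25_000,
                 tss_window: int = 2_000) -> set[str]:
    """Genes attributable to a risk locus.

    The union of (a) genes whose span lies within ``near_window`` bp of the
    locus span, and (b) genes whose promoter (TSS +/- ``tss_window``,
    inclusive) intersects a long-range interaction target anchored at the
    locus.
    """
    chrom, start, end = locus.span
    out: set[str] = set()
    for g in genes:
        if (
            g.chrom == chrom
            and g.start < end + near_window
            and g.end > start - near_window
        ):
            out.add(g.gene_id)
    if interactions is not None:
        targets = [it.target for it in interactions.for_locus(locus)]
        for g in genes:
            promoter = Region(
                g.chrom, max(g.tss - tss_window, 0), g.tss + tss_window + 1
            )
            if any(promoter.overlaps(t) for t in targets):
                out.add(g.gene_id)
    return out
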