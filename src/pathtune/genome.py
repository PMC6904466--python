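"""Genome coordinate space: an ordered set of named chromosomes with lengths.

All coordinates in the package are 0-based, half-open (BED convention); a SNP
at base ``k`` occupies the interval ``[k, k+1)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import PlanError


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise PlanError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise PlanError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise PlanError("chromosome lengths must be positive")
        object.__setattr__(
            self, "_index", dict(zip(self.chrom_names, self.chrom_lengths))
        )

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise PlanError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom_names, "length": self.chrom_lengths}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))
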