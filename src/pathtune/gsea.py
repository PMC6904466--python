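"""Pre-ranked weighted gene-set enrichment.

Genes are ranked by a combined differential-expression metric

    pi = phi * (-log10 pv)

where ``phi`` is the log2 fold-change and ``pv`` the per-gene p-value, so
that strongly up-regulated, strongly significant genes sit at the top of the
list and strongly down-regulated ones at the bottom.

The enrichment score walks the ranked list: set members increment the
running sum proportionally to |pi|**weight (normalised over the set),
non-members decrement it by 1/(N - N_set); the ES is the extremum of
largest magnitude. ``weight=0`` recovers the classic Kolmogorov-Smirnov
statistic. Significance comes from random same-size gene-label sets; the
NES divides the ES by the mean |null ES| of matching sign, and the one-sided
p is the fraction of same-sign null scores at least as extreme.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptySetError

__all__ = [
    "RankedGene",
    "GeneSet",
    "GseaResult",
    "rank_metric",
    "rank_table",
    "enrichment_score",
    "gsea_test",
]


@dataclass(frozen=True)
class RankedGene:
    """One gene's differential-expression summary and ranking metric."""

    gene_id: str
    phi: float  # log2 fold-change
    pv: float  # differential-expression p-value
    pi: float  # ranking metric phi * (-log10 pv)


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptySetError(f"gene set {self.label!r} is empty")


@dataclass
class GseaResult:
    es: float
    nes: float
    p_perm: float
    p_is_bound: bool
    running_sum: np.ndarray
    ranked_genes: tuple[str, ...]
    hit_ranks: tuple[int, ...]
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "es": float(self.es),
            "nes": float(self.nes),
            "p_perm": float(self.p_perm),
            "p_is_bound": bool(self.p_is_bound),
            "n_perm": int(self.n_perm),
            "n_genes": len(self.ranked_genes),
            "n_hits": len(self.hit_ranks),
            "hit_ranks": [int(r) for r in self.hit_ranks],
            "running_sum": [round(float(v), 6) for v in self.running_sum],
        }


def rank_metric(phi, pv):
    """pi = phi * (-log10 pv); the sign follows the fold-change."""
    phi = np.asarray(phi, dtype=float)
    pv = np.asarray(pv, dtype=float)
    if np.any(pv <= 0) or np.any(pv > 1):
        raise ValueError("p-values must lie in (0, 1]")
    pi = phi * (-np.log10(pv))
    return float(pi) if pi.ndim == 0 else pi


def rank_table(df: pd.DataFrame) -> list[RankedGene]:
    """Build a ranked list from a DataFrame with columns gene, phi, pv
    (or gene, pi). Sorted by pi descending, ties broken by gene id."""
    if {"phi", "pv"}.issubset(df.columns):
        pi = rank_metric(df["phi"].to_numpy(), df["pv"].to_numpy())
        genes = [
            RankedGene(str(g), float(f), float(p), float(m))
            for g, f, p, m in zip(df["gene"], df["phi"], df["pv"], pi)
        ]
    elif "pi" in df.columns:
        genes = [
            RankedGene(str(g), float("nan"), float("nan"), float(m))
            for g, m in zip(df["gene"], df["pi"])
        ]
    else:
        raise ValueError("need columns (gene, phi, pv) or (gene, pi)")
    genes.sort(key=lambda g: (-g.pi, g.gene_id))
    return genes


def _ordered(ranked: Sequence[RankedGene]) -> tuple[list[str], np.ndarray]:
    pairs = sorted(ranked, key=lambda g: (-g.pi, g.gene_id))
    return [g.gene_id for g in pairs], np.array([g.pi for g in pairs])


def _es_from_mask(pi: np.ndarray, hits: np.ndarray,
                  weight: float) -> tuple[float, np.ndarray]:
    n = len(pi)
    n_hit = int(hits.sum())
    w = np.abs(pi) ** weight
    denom = w[hits].sum()
    inc = np.zeros(n)
    if denom > 0:
        inc[hits] = w[hits] / denom
    else:  # all member metrics are exactly zero: fall back to equal steps
        inc[hits] = 1.0 / n_hit
    inc[~hits] = -1.0 / (n - n_hit)
    running = np.cumsum(inc)
    k = int(np.argmax(np.abs(running)))
    return float(running[k]), running


def enrichment_score(ranked: Sequence[RankedGene], gene_set: GeneSet,
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score for one gene set.

    Returns (es, running_sum); ``running_sum`` has one entry per ranked gene.
    Set members absent from the ranked universe are dropped.
    """
    order, pi = _ordered(ranked)
    hits = np.array([g in gene_set.members for g in order])
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise EmptySetError(
            f"gene set {gene_set.label!r} has no member in the ranked universe"
        )
    if n_hit == len(order):
        raise ConfigError("gene set covers the whole universe")
    return _es_from_mask(pi, hits, weight)


def gsea_test(ranked: Sequence[RankedGene], gene_set: GeneSet,
              n_perm: int = 10_000, seed: int | None = None,
              weight: float = 1.0) -> GseaResult:
    """Permutation significance for the enrichment score.

    The null draws ``n_perm`` random gene-label sets of the same size from
    the ranked universe. ``p_perm`` is the fraction of same-sign null scores
    with magnitude >= |ES| among same-sign nulls; NES = ES / mean(|null ES|
    of matching sign).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    order, pi = _ordered(ranked)
    hits = np.array([g in gene_set.members for g in order])
    n = len(order)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise EmptySetError(
            f"gene set {gene_set.label!r} has no member in the ranked universe"
        )
    if n_hit == n:
        raise ConfigError("gene set covers the whole universe")
    es, running = _es_from_mask(pi, hits, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_hit, replace=False)
        mask[:] = False
        mask[idx] = True
        null[i], _ = _es_from_mask(pi, mask, weight)

    same_sign = null * np.sign(es) > 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        p, bound, nes = 0.0, True, float("nan")
    else:
        m = int((np.abs(null[same_sign]) >= abs(es)).sum())
        bound = m == 0
        p = float(m / n_same) if m else 0.0
        nes = float(es / np.abs(null[same_sign]).mean())
    return GseaResult(
        es=es, nes=nes, p_perm=p, p_is_bound=bound, running_sum=running,
        ranked_genes=tuple(order),
        hit_ranks=tuple(int(i) for i in np.flatnonzero(hits)),
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], frozenset(parts[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write(
                "\t".join([gs.label, "na"] + sorted(gs.members)) + "\n"
            )
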