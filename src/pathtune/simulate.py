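"""Synthetic data generator for the whole pipeline, with planted ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* an LD-block-structured genotype panel (stand-in for a reference panel such
  as 1000 Genomes CEU) built by block-copy-with-flip: within a block every
  dosage column is a copy of a template with per-entry resampling probability
  tuned so pairwise r^2 concentrates near the target; different blocks are
  independent;
* GWAS summary statistics with planted genome-wide-significant associations:
  a configurable number of causal blocks whose index SNP lies inside a
  ChIP-seq peak, a number lying outside all peaks, attenuated p-values for
  linked SNPs, and i.i.d. Uniform(0,1) p-values elsewhere;
* binding-site peaks (with replicate datasets for consensus construction),
  enhancer background regions, gene models and a long-range interaction
  table;
* negative-binomial count matrices with planted condition and genotype
  effects (mean = baseline * 2**(effect * covariate), NB2 dispersion).

Same seed, same bytes: every output is a deterministic function of the plan
and seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import PlanError, SizingError
from .genome import GenomeLayout
from .intervals import (GeneModel, Interaction, InteractionTable, Region,
                        RegionSet, write_genes)
from .ldloci import GenotypePanel, SummaryStats

__all__ = [
    "SimulationPlan",
    "make_genome",
    "simulate_panel",
    "simulate_features",
    "replicate_peak_sets",
    "simulate_gwas",
    "simulate_genes",
    "simulate_counts",
    "write_dataset",
]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class SimulationPlan:
    """All knobs of the synthetic study, with defaults that constitute the
    study conditions exercised by the tests: a 20-Mb toy genome, 12 planted
    causal loci of which half sit inside binding-site peaks, peaks covering
    well under 1% of the genome, and moderately overdispersed counts."""

    seed: int = 0
    # genome
    chrom_lengths: tuple = (5_000_000, 5_000_000, 5_000_000, 5_000_000)
    # panel
    n_samples: int = 100
    n_snps: int = 2_600
    snps_per_block: int = 10
    ld_block_len: int = 25_000
    within_block_r2: float = 0.9
    maf_range: tuple = (0.1, 0.5)
    # planted associations
    n_causal_in_peaks: int = 6
    n_causal_outside: int = 6
    causal_spacing: int = 600_000
    # features
    peak_count: int = 100
    peak_len_range: tuple = (400, 1_200)
    enhancer_count: int = 300
    enhancer_len_range: tuple = (1_000, 3_000)
    frac_peaks_in_enhancers: float = 0.8
    n_peak_datasets: int = 3
    peak_jitter: int = 80
    # genes / counts
    n_genes: int = 400
    gene_len_range: tuple = (5_000, 30_000)
    nb_mean_range: tuple = (50.0, 2_000.0)
    nb_dispersion: float = 0.05
    condition_log2fc_effects: dict = field(default_factory=dict)
    genotype_log2fc_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [
            self.n_samples, self.n_snps, self.snps_per_block,
            self.ld_block_len, self.n_causal_in_peaks, self.n_causal_outside,
            self.peak_count, self.enhancer_count, self.n_peak_datasets,
            self.n_genes,
        ]
        if any(c < 0 for c in counts):
            raise PlanError("all counts must be >= 0")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise PlanError("within_block_r2 must lie in [0, 1]")
        if not (0.0 <= self.frac_peaks_in_enhancers <= 1.0):
            raise PlanError("frac_peaks_in_enhancers must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise PlanError("nb_dispersion must be > 0")
        if any(l <= 0 for l in self.chrom_lengths):
            raise PlanError("chromosome lengths must be positive")
        for lo, hi in (self.peak_len_range, self.enhancer_len_range,
                       self.gene_len_range, self.nb_mean_range,
                       self.maf_range):
            if not (0 < lo <= hi):
                raise PlanError("ranges must satisfy 0 < low <= high")

    @property
    def n_blocks(self) -> int:
        return self.n_snps // self.snps_per_block

    # -- YAML --------------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationPlan":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise PlanError(f"unknown plan field {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# genome & panel
# ---------------------------------------------------------------------------

def make_genome(plan: SimulationPlan) -> GenomeLayout:
    """Coordinate space for the plan; errors if the requested features cannot
    physically fit."""
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(len(plan.chrom_lengths))),
        tuple(int(x) for x in plan.chrom_lengths),
    )
    footprint = (
        plan.n_blocks * plan.ld_block_len
        + plan.peak_count * plan.peak_len_range[1]
        + plan.enhancer_count * plan.enhancer_len_range[1]
    )
    if footprint > layout.total_length:
        raise SizingError(
            f"feature footprint {footprint} bp exceeds genome length "
            f"{layout.total_length} bp"
        )
    return layout


def _draw_polymorphic(rng, maf: float, n: int) -> np.ndarray:
    for _ in range(200):
        col = rng.binomial(2, maf, size=n)
        if col.min() != col.max():
            return col
    raise SizingError("could not draw a polymorphic dosage column")


def simulate_panel(plan: SimulationPlan, genome: GenomeLayout,
                   rng: np.random.Generator | None = None) -> GenotypePanel:
    """LD-block-structured dosage panel.

    Blocks are laid on a non-overlapping grid (grid cell = block length),
    allocated to chromosomes in proportion to length. Within a block each
    SNP copies the block template, with each entry independently resampled
    from the marginal with probability eps. A flipped copy correlates with
    the template at (1 - eps), so two block members correlate at
    (1 - eps)^2 and their r^2 is (1 - eps)^4; eps = 1 - r2^(1/4) puts
    pairwise r^2 at the target. No SNP is monomorphic (the MAF floor is
    enforced by redrawing).
    """
    if plan.n_samples < 2:
        raise PlanError("n_samples must be >= 2")
    rng = rng or np.random.default_rng(plan.seed)
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    n_blocks = plan.n_blocks
    alloc = np.floor(n_blocks * lengths / lengths.sum()).astype(int)
    while alloc.sum() < n_blocks:
        alloc[int(np.argmax(lengths / (alloc + 1)))] += 1

    eps = 1.0 - plan.within_block_r2 ** 0.25
    step = max(plan.ld_block_len // plan.snps_per_block, 1)
    cols, ids, chroms, poss, block_ids = [], [], [], [], []
    snp_i = 0
    block_i = 0
    for ci, chrom in enumerate(genome.chrom_names):
        n_slots = int(lengths[ci]) // plan.ld_block_len
        if alloc[ci] > n_slots:
            raise SizingError(
                f"{alloc[ci]} blocks do not fit on {chrom} "
                f"({n_slots} slots of {plan.ld_block_len} bp)"
            )
        slots = np.sort(
            rng.choice(n_slots, size=alloc[ci], replace=False)
        )
        for slot in slots:
            start = int(slot) * plan.ld_block_len
            maf = rng.uniform(*plan.maf_range)
            template = _draw_polymorphic(rng, maf, plan.n_samples)
            for j in range(plan.snps_per_block):
                pos = start + j * step + int(rng.integers(0, max(step // 2, 1)))
                col = template.copy()
                if eps > 0:
                    flip = rng.random(plan.n_samples) < eps
                    if flip.any():
                        col[flip] = rng.binomial(2, maf, size=int(flip.sum()))
                    if col.min() == col.max():  # keep the MAF floor honest
                        col = template.copy()
                cols.append(col)
                ids.append(f"rs{snp_i + 1}")
                chroms.append(chrom)
                poss.append(pos)
                block_ids.append(block_i)
                snp_i += 1
            block_i += 1
    return GenotypePanel(
        np.column_stack(cols), ids, chroms, poss, block_ids=np.array(block_ids)
    )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng, genome: GenomeLayout, n: int,
                          len_range, taken: list, name_prefix: str,
                          inside: RegionSet | None = None) -> list[Region]:
    """Uniform random placement avoiding previously placed regions.

    ``inside`` constrains placement to a background region set (destination
    region chosen with probability proportional to its number of valid start
    positions).
    """
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    out = []
    for k in range(n):
        L = int(rng.integers(len_range[0], len_range[1] + 1))
        for _ in range(200):
            if inside is None:
                slots = np.maximum(lengths - L + 1, 0)
                if slots.sum() == 0:
                    raise SizingError(f"feature of length {L} fits nowhere")
                ci = int(rng.choice(len(lengths), p=slots / slots.sum()))
                chrom = genome.chrom_names[ci]
                start = int(rng.integers(0, int(lengths[ci]) - L + 1))
            else:
                bg = inside.df
                bg_len = (bg["end"] - bg["start"]).to_numpy()
                slots = np.maximum(bg_len - L + 1, 0).astype(float)
                if slots.sum() == 0:
                    raise SizingError(
                        f"feature of length {L} fits in no background region"
                    )
                ri = int(rng.choice(len(bg), p=slots / slots.sum()))
                chrom = str(bg["chrom"].iat[ri])
                start = int(
                    rng.integers(bg["start"].iat[ri], bg["end"].iat[ri] - L + 1)
                )
            if not any(
                c == chrom and s < start + L and start < e
                for c, s, e in taken
            ):
                break
        else:
            raise SizingError(f"could not place feature {name_prefix}{k}")
        taken.append((chrom, start, start + L))
        out.append(Region(chrom, start, start + L, f"{name_prefix}{k + 1}"))
    return out


def simulate_features(plan: SimulationPlan, genome: GenomeLayout,
                      panel: GenotypePanel,
                      rng: np.random.Generator | None = None
                      ) -> tuple[RegionSet, RegionSet]:
    """Binding-site peaks and enhancer background regions.

    ``n_causal_in_peaks`` peaks are deliberately centred on SNPs from
    mutually well-separated LD blocks so the GWAS simulation can plant
    in-peak associations; the rest are placed inside enhancers (a
    ``frac_peaks_in_enhancers`` share) or uniformly. Peaks do not overlap
    one another.
    """
    rng = rng or np.random.default_rng(plan.seed + 1)
    taken_enh: list = []
    enhancers = _place_nonoverlapping(
        rng, genome, plan.enhancer_count, plan.enhancer_len_range,
        taken_enh, "enh",
    )
    enh_set = RegionSet.from_regions(enhancers, label="enhancers")

    taken_peaks: list = []
    peaks: list[Region] = []
    # planted peaks over well-separated blocks
    n_plant = plan.n_causal_in_peaks
    if n_plant:
        blocks = _spaced_blocks(plan, panel, rng, n_plant, avoid=[])
        for k, b in enumerate(blocks):
            snps = np.flatnonzero(panel.block_ids == b)
            j = snps[len(snps) // 2]
            pos = int(panel.pos[j])
            chrom = str(panel.chrom[j])
            L = int(rng.integers(plan.peak_len_range[0],
                                 plan.peak_len_range[1] + 1))
            margin = plan.peak_jitter + 50
            lo = max(pos - L + 1 + margin, 0)
            hi = max(pos - margin, lo)
            start = int(rng.integers(lo, hi + 1))
            start = min(start, genome.length_of(chrom) - L)
            peaks.append(Region(chrom, start, start + L, f"peak_p{k + 1}"))
            taken_peaks.append((chrom, start, start + L))
    n_rest = max(plan.peak_count - len(peaks), 0)
    n_in_enh = int(round(plan.frac_peaks_in_enhancers * n_rest))
    peaks += _place_nonoverlapping(
        rng, genome, n_in_enh, plan.peak_len_range, taken_peaks, "peak_e",
        inside=enh_set,
    )
    peaks += _place_nonoverlapping(
        rng, genome, n_rest - n_in_enh, plan.peak_len_range, taken_peaks,
        "peak_g",
    )
    return RegionSet.from_regions(peaks, label="binding-sites"), enh_set


def replicate_peak_sets(plan: SimulationPlan, peaks: RegionSet,
                        genome: GenomeLayout,
                        rng: np.random.Generator | None = None
                        ) -> list[RegionSet]:
    """Per-dataset replicate peak calls whose consensus recovers ``peaks``.

    Every true peak appears, edge-jittered by up to ``peak_jitter`` bp, in at
    least two (randomly chosen) datasets; each dataset also carries its own
    unsupported noise peaks, which a >=2-dataset consensus discards.
    """
    rng = rng or np.random.default_rng(plan.seed + 2)
    n_ds = plan.n_peak_datasets
    if n_ds < 2:
        raise PlanError("need at least two peak datasets for a consensus")
    per_ds: list[list[Region]] = [[] for _ in range(n_ds)]
    taken = [(r.chrom, r.start, r.end) for r in peaks]
    for region in peaks:
        support = int(rng.integers(2, n_ds + 1))
        chosen = rng.choice(n_ds, size=support, replace=False)
        for ds in chosen:
            j1 = int(rng.integers(-plan.peak_jitter, plan.peak_jitter + 1))
            j2 = int(rng.integers(-plan.peak_jitter, plan.peak_jitter + 1))
            start = max(region.start + j1, 0)
            end = max(region.end + j2, start + 1)
            per_ds[int(ds)].append(
                Region(region.chrom, start, end, region.name)
            )
    n_noise = max(plan.peak_count // 5, 1)
    # noise avoids true peaks and all other noise (also across datasets), so
    # no unsupported cluster can reach the consensus support threshold
    noise_taken = list(taken)
    for ds in range(n_ds):
        noise = _place_nonoverlapping(
            rng, genome, n_noise, plan.peak_len_range, noise_taken,
            f"noise_d{ds + 1}_",
        )
        per_ds[ds].extend(noise)
    return [
        RegionSet.from_regions(regions, label=f"dataset_{ds + 1}")
        for ds, regions in enumerate(per_ds)
    ]


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def _block_positions(panel: GenotypePanel, block: int) -> tuple[str, int]:
    snps = np.flatnonzero(panel.block_ids == block)
    return str(panel.chrom[snps[0]]), int(panel.pos[snps].mean())


def _spaced_blocks(plan: SimulationPlan, panel: GenotypePanel, rng,
                   n: int, avoid: list, candidates=None) -> list[int]:
    """Pick n blocks pairwise (and vs ``avoid``) separated by
    ``causal_spacing`` on the same chromosome."""
    if candidates is None:
        candidates = np.unique(panel.block_ids)
    candidates = np.asarray(candidates)
    order = rng.permutation(len(candidates))
    chosen: list[int] = []
    anchors = [ _block_positions(panel, b) for b in avoid ]
    for i in order:
        b = int(candidates[i])
        chrom, pos = _block_positions(panel, b)
        if all(
            c != chrom or abs(p - pos) >= plan.causal_spacing
            for c, p in anchors
        ):
            chosen.append(b)
            anchors.append((chrom, pos))
            if len(chosen) == n:
                return chosen
    raise SizingError(
        f"could not select {n} blocks separated by {plan.causal_spacing} bp"
    )


def simulate_gwas(plan: SimulationPlan, genome: GenomeLayout,
                  panel: GenotypePanel, peaks: RegionSet,
                  rng: np.random.Generator | None = None
                  ) -> tuple[SummaryStats, pd.DataFrame]:
    """Summary statistics with planted associations.

    ``n_causal_in_peaks`` causal blocks get an index SNP lying inside a peak,
    ``n_causal_outside`` get one with no peak contact; all index p-values
    fall below genome-wide significance (10**-U(9, 20)), linked SNPs in the
    same block receive attenuated p-values (log10 p scaled by U(0.4, 0.85)),
    and every other SNP draws p ~ Uniform(0, 1). Causal blocks are mutually
    separated by ``causal_spacing`` so clumping can resolve them.

    Returns (stats, truth), where truth lists each causal block's index SNP
    and whether it was planted inside a peak.
    """
    rng = rng or np.random.default_rng(plan.seed + 3)
    n_snps = panel.n_snps
    pvals = rng.uniform(np.nextafter(0, 1), 1.0, size=n_snps)

    in_peak = np.zeros(n_snps, dtype=bool)
    for chrom in np.unique(panel.chrom):
        sel = panel.chrom == chrom
        in_peak[sel] = peaks.positions_in(str(chrom), panel.pos[sel])

    blocks = np.unique(panel.block_ids)
    block_has_peak = {
        int(b): bool(in_peak[panel.block_ids == b].any()) for b in blocks
    }
    cand_in = [b for b in blocks if block_has_peak[int(b)]]
    cand_out = [b for b in blocks if not block_has_peak[int(b)]]
    if len(cand_in) < plan.n_causal_in_peaks:
        raise SizingError(
            f"only {len(cand_in)} blocks contain a SNP inside a peak; "
            f"{plan.n_causal_in_peaks} requested"
        )
    chosen_in = _spaced_blocks(plan, panel, rng, plan.n_causal_in_peaks,
                               avoid=[], candidates=cand_in) \
        if plan.n_causal_in_peaks else []
    chosen_out = _spaced_blocks(plan, panel, rng, plan.n_causal_outside,
                                avoid=chosen_in, candidates=cand_out) \
        if plan.n_causal_outside else []

    truth_rows = []
    for b, planted_in_peak in (
        [(b, True) for b in chosen_in] + [(b, False) for b in chosen_out]
    ):
        snps = np.flatnonzero(panel.block_ids == b)
        if planted_in_peak:
            index = snps[in_peak[snps]][0]
        else:
            index = snps[len(snps) // 2]
        log10p = -rng.uniform(9.0, 20.0)
        pvals[index] = 10.0 ** log10p
        for j in snps:
            if j != index:
                pvals[j] = 10.0 ** (log10p * rng.uniform(0.4, 0.85))
        truth_rows.append(
            {
                "block": int(b),
                "index_snp": str(panel.snp_ids[index]),
                "chrom": str(panel.chrom[index]),
                "pos": int(panel.pos[index]),
                "in_peak": planted_in_peak,
            }
        )
    stats = SummaryStats(
        pd.DataFrame(
            {
                "chrom": panel.chrom,
                "pos": panel.pos,
                "snp_id": panel.snp_ids,
                "pvalue": pvals,
            }
        )
    )
    truth = pd.DataFrame(
        truth_rows, columns=["block", "index_snp", "chrom", "pos", "in_peak"]
    ).sort_values("block").reset_index(drop=True)
    return stats, truth


# ---------------------------------------------------------------------------
# genes & counts
# ---------------------------------------------------------------------------

def simulate_genes(plan: SimulationPlan, genome: GenomeLayout,
                   rng: np.random.Generator | None = None) -> list[GeneModel]:
    rng = rng or np.random.default_rng(plan.seed + 4)
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    genes = []
    for k in range(plan.n_genes):
        L = int(rng.integers(plan.gene_len_range[0],
                             plan.gene_len_range[1] + 1))
        slots = np.maximum(lengths - L + 1, 0)
        ci = int(rng.choice(len(lengths), p=slots / slots.sum()))
        start = int(rng.integers(0, int(lengths[ci]) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + L - 1
        genes.append(
            GeneModel(f"G{k + 1:04d}", genome.chrom_names[ci], start,
                      start + L, strand, tss)
        )
    return genes


def simulate_counts(plan: SimulationPlan, n_genes: int, group_labels,
                    genotypes=None,
                    rng: np.random.Generator | None = None,
                    gene_ids=None, sample_ids=None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix with planted condition and genotype effects.

    Mean for gene i in sample j: baseline_i * 2**(phi_cond_i * cond_j)
    * 2**(phi_geno_i * geno_j); counts are NB2 with the plan's dispersion.
    Effects come from the plan's ``condition_log2fc_effects`` /
    ``genotype_log2fc_effects`` dicts keyed by gene id (genes not listed get
    zero effect). Returns (counts, truth).
    """
    rng = rng or np.random.default_rng(plan.seed + 5)
    cond = np.asarray(group_labels, dtype=float)
    n_samples = len(cond)
    if genotypes is not None:
        geno = np.asarray(genotypes, dtype=float)
        if len(geno) != n_samples:
            raise PlanError("genotype vector length mismatch")
    else:
        geno = np.zeros(n_samples)
    if gene_ids is None:
        gene_ids = [f"G{k + 1:04d}" for k in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise PlanError("gene_ids length mismatch")
    if sample_ids is None:
        sample_ids = [f"S{j + 1}" for j in range(n_samples)]

    lo, hi = plan.nb_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    phi_c = np.array(
        [plan.condition_log2fc_effects.get(g, 0.0) for g in gene_ids]
    )
    phi_g = np.array(
        [plan.genotype_log2fc_effects.get(g, 0.0) for g in gene_ids]
    )
    mu = baseline[:, None] * 2.0 ** (
        phi_c[:, None] * cond[None, :] + phi_g[:, None] * geno[None, :]
    )
    alpha = plan.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene"
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "baseline": baseline,
            "condition_log2fc": phi_c,
            "genotype_log2fc": phi_g,
        }
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

def _near_block_genes(genes, panel, blocks, window=25_000) -> list[str]:
    out = []
    for g in genes:
        for b in blocks:
            snps = np.flatnonzero(panel.block_ids == b)
            if str(panel.chrom[snps[0]]) != g.chrom:
                continue
            lo, hi = panel.pos[snps].min(), panel.pos[snps].max() + 1
            if g.start < hi + window and g.end > lo - window:
                out.append(g.gene_id)
                break
    return out


def write_dataset(plan: SimulationPlan, outdir, seed: int | None = None) -> dict:
    """Generate and write every pipeline input; returns paths and objects.

    Planted expression truth: genes lying within 25 kb of a causal block are
    up-regulated in the "active" condition (log2FC +2, emulating
    pathway-target induction near risk loci) and respond additively to the
    genotype of the first planted in-peak index SNP (log2FC +1 per allele);
    a background 10% of other genes get condition effects of either sign.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = plan.seed if seed is None else seed
    plan = dataclasses.replace(plan, seed=seed)
    rng = np.random.default_rng(seed)

    genome = make_genome(plan)
    panel = simulate_panel(plan, genome, rng)
    peaks, enhancers = simulate_features(plan, genome, panel, rng)
    peak_sets = replicate_peak_sets(plan, peaks, genome, rng)
    stats, gwas_truth = simulate_gwas(plan, genome, panel, peaks, rng)
    genes = simulate_genes(plan, genome, rng)

    causal_blocks = gwas_truth["block"].tolist()
    near = _near_block_genes(genes, panel, causal_blocks)
    cond_fx = dict(plan.condition_log2fc_effects)
    geno_fx = dict(plan.genotype_log2fc_effects)
    if not cond_fx:
        cond_fx = {g: 2.0 for g in near}
        others = [g.gene_id for g in genes if g.gene_id not in cond_fx]
        n_bg = len(others) // 10
        bg = rng.choice(len(others), size=n_bg, replace=False)
        for i, k in enumerate(bg):
            cond_fx[others[int(k)]] = 1.5 if i % 2 == 0 else -1.5
    if not geno_fx:
        geno_fx = {g: 1.0 for g in near}
    plan_fx = dataclasses.replace(
        plan,
        condition_log2fc_effects=cond_fx,
        genotype_log2fc_effects=geno_fx,
    )
    gene_ids = [g.gene_id for g in genes]

    # condition design: 3 vs 3 (stand-in for a cell-line +/- rescue contrast)
    cond_labels = np.array([1, 1, 1, 0, 0, 0])
    cond_samples = [f"C{j + 1}" for j in range(6)]
    counts_cond, truth_cond = simulate_counts(
        plan_fx, plan.n_genes, cond_labels, rng=rng, gene_ids=gene_ids,
        sample_ids=cond_samples,
    )

    # genotype design: panel samples, dosage of the first in-peak index SNP
    eqtl_snp = gwas_truth.loc[gwas_truth["in_peak"], "index_snp"].iloc[0] \
        if gwas_truth["in_peak"].any() else gwas_truth["index_snp"].iloc[0]
    geno_vec = panel.column(eqtl_snp).astype(int)
    counts_geno, truth_geno = simulate_counts(
        plan_fx, plan.n_genes, np.zeros(panel.n_samples), genotypes=geno_vec,
        rng=rng, gene_ids=gene_ids, sample_ids=list(panel.sample_ids),
    )

    # paired tumour/normal design: condition effect applied within pairs
    n_pairs = 30
    pair_labels = np.array([1, 0] * n_pairs)
    pair_samples = [
        f"P{j // 2 + 1}{'T' if j % 2 == 0 else 'N'}" for j in range(2 * n_pairs)
    ]
    counts_paired, _ = simulate_counts(
        plan_fx, plan.n_genes, pair_labels, rng=rng, gene_ids=gene_ids,
        sample_ids=pair_samples,
    )

    # long-range interactions: two causal blocks contact a distal gene
    # promoter (>=100 kb away), exercising interaction-based assignment
    interactions = []
    for b in causal_blocks[:2]:
        snps = np.flatnonzero(panel.block_ids == b)
        chrom = str(panel.chrom[snps[0]])
        lo, hi = int(panel.pos[snps].min()), int(panel.pos[snps].max()) + 1
        distal = [
            g for g in genes
            if g.chrom == chrom and abs(g.tss - lo) > 100_000
        ]
        if not distal:
            continue
        g = distal[int(rng.integers(0, len(distal)))]
        interactions.append(
            Interaction(
                target=Region(g.chrom, max(g.tss - 1_000, 0), g.tss + 1_000),
                viewpoint=Region(chrom, lo, hi),
            )
        )
    itable = InteractionTable(interactions)

    paths = {
        "plan": outdir / "plan.yaml",
        "genome": outdir / "genome.tsv",
        "panel_vcf": outdir / "panel.vcf",
        "panel_dosage": outdir / "dosages.tsv",
        "stats": outdir / "stats.tsv",
        "enhancers": outdir / "enhancers.bed",
        "peaks_true": outdir / "peaks_true.bed",
        "genes": outdir / "genes.tsv",
        "interactions": outdir / "interactions.tsv",
        "gwas_truth": outdir / "gwas_truth.tsv",
        "counts_condition": outdir / "counts_condition.tsv",
        "samples_condition": outdir / "samples_condition.tsv",
        "counts_genotype": outdir / "counts_genotype.tsv",
        "samples_genotype": outdir / "samples_genotype.tsv",
        "counts_paired": outdir / "counts_paired.tsv",
        "samples_paired": outdir / "samples_paired.tsv",
        "expression_truth": outdir / "expression_truth.tsv",
    }
    plan_fx.to_yaml(paths["plan"])
    genome.to_tsv(paths["genome"])
    panel.to_vcf(paths["panel_vcf"], genome)
    panel.to_dosage_tsv(paths["panel_dosage"])
    stats.to_tsv(paths["stats"])
    enhancers.to_bed(paths["enhancers"])
    peaks.to_bed(paths["peaks_true"])
    peak_set_paths = []
    for i, ps in enumerate(peak_sets):
        p = outdir / f"peaks_ds{i + 1}.bed"
        ps.to_bed(p)
        peak_set_paths.append(p)
    paths["peak_sets"] = peak_set_paths
    write_genes(genes, paths["genes"])
    itable.to_tsv(paths["interactions"])
    gwas_truth.to_csv(paths["gwas_truth"], sep="\t", index=False)
    counts_cond.to_csv(paths["counts_condition"], sep="\t")
    pd.DataFrame(
        {"sample": cond_samples, "condition": cond_labels}
    ).to_csv(paths["samples_condition"], sep="\t", index=False)
    counts_geno.to_csv(paths["counts_genotype"], sep="\t")
    pd.DataFrame(
        {"sample": list(panel.sample_ids), "genotype": geno_vec}
    ).to_csv(paths["samples_genotype"], sep="\t", index=False)
    counts_paired.to_csv(paths["counts_paired"], sep="\t")
    pd.DataFrame(
        {
            "sample": pair_samples,
            "tissue": ["tumour" if l else "normal" for l in pair_labels],
            "pair_id": [f"P{j // 2 + 1}" for j in range(2 * n_pairs)],
        }
    ).to_csv(paths["samples_paired"], sep="\t", index=False)
    truth_cond.assign(eqtl_snp=eqtl_snp).to_csv(
        paths["expression_truth"], sep="\t", index=False,
        float_format="%.6g",
    )

    return {
        "paths": paths,
        "plan": plan_fx,
        "genome": genome,
        "panel": panel,
        "peaks": peaks,
        "enhancers": enhancers,
        "peak_sets": peak_sets,
        "stats": stats,
        "gwas_truth": gwas_truth,
        "genes": genes,
        "interactions": itable,
        "eqtl_snp": eqtl_snp,
    }
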