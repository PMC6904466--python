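"""Orchestration of the full analysis.

Stages, in dependency order: load inputs -> consensus peaks -> clump
supra/sub loci -> permutation overlap tests (loci-shuffled direct overlap,
loci-shuffled +/-25 kb proximity, peaks-shuffled within enhancers) -> gene
assignment per locus -> condition rank table + gene-set enrichment ->
genotype NB-LRT association -> paired tumour/normal comparison -> report.

One global seed is expanded into independent per-stage seeds, so the report
is a deterministic function of (config, input files).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .expression import (CountMatrix, differential_rank_table, lrt_genotype,
                         paired_test, size_factors)
from .genome import GenomeLayout
from .gsea import GeneSet, gsea_test
from .intervals import (InteractionTable, RegionSet, assign_genes,
                        consensus_peaks, read_genes)
from .ldloci import ClumpConfig, GenotypePanel, SummaryStats, clump
from .permutation import ShuffleConfig, locus_shuffle_test, peak_shuffle_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisReport", "run_full", "summarize"]


@dataclass
class RunConfig:
    """Paths and parameters for a full run. Paths are resolved relative to
    the config file's directory when loaded from YAML."""

    # inputs
    genome: str = ""
    stats: str = ""
    panel: str = ""  # .vcf or dosage .tsv
    peak_beds: list = field(default_factory=list)
    enhancers: str = ""
    genes: str = ""
    interactions: str = ""
    counts_condition: str = ""
    samples_condition: str = ""
    counts_genotype: str = ""
    samples_genotype: str = ""
    counts_paired: str = ""
    samples_paired: str = ""
    # parameters
    seed: int = 0
    min_datasets: int = 2
    p_threshold: float = 5e-8
    p_window_low: float = 1e-4
    exclude_dist: int = 500_000
    exclude_r2: float = 0.2
    block_r2: float = 0.8
    n_iter: int = 10_000
    proximity_window: int = 25_000
    overlap_mode: str = "snp"
    gsea_weight: float = 1.0
    gsea_n_perm: int = 2_000
    eqtl_coding: str = "additive"
    eqtl_max_genes: int = 50
    outdir: str = "pathtune_run"

    def clump_config(self) -> ClumpConfig:
        return ClumpConfig(
            p_threshold=self.p_threshold, p_window_low=self.p_window_low,
            exclude_dist=self.exclude_dist, exclude_r2=self.exclude_r2,
            block_r2=self.block_r2,
        )

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")
        if self.gsea_n_perm < 1:
            raise ConfigError("gsea_n_perm must be >= 1")
        self.clump_config()  # raises on bad thresholds
        required = {
            "genome": self.genome, "stats": self.stats, "panel": self.panel,
        }
        for stage, p in required.items():
            if not p or not Path(p).exists():
                raise ConfigError(f"missing input for stage {stage!r}: {p!r}")
        if not self.peak_beds:
            raise ConfigError("missing input for stage 'consensus': peak_beds")
        for p in self.peak_beds:
            if not Path(p).exists():
                raise ConfigError(f"missing input for stage 'consensus': {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        base = path.parent
        for f in ("genome", "stats", "panel", "enhancers", "genes",
                  "interactions", "counts_condition", "samples_condition",
                  "counts_genotype", "samples_genotype", "counts_paired",
                  "samples_paired", "outdir"):
            v = getattr(cfg, f)
            if v:
                setattr(cfg, f, str((base / v) if not Path(v).is_absolute() else Path(v)))
        cfg.peak_beds = [
            str((base / p) if not Path(p).is_absolute() else Path(p))
            for p in cfg.peak_beds
        ]
        return cfg


@dataclass
class AnalysisReport:
    """Per-stage results, config echo and software version; JSON-serialisable."""

    content: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.content, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __getitem__(self, key):
        return self.content[key]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def run_full(config: RunConfig) -> AnalysisReport:
    """Execute every stage; any failure aborts with the stage name."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    stage = "load"
    try:
        genome = GenomeLayout.from_tsv(config.genome)
        stats = SummaryStats.read_tsv(config.stats)
        panel = (
            GenotypePanel.from_vcf(config.panel)
            if str(config.panel).endswith(".vcf")
            else GenotypePanel.from_dosage_tsv(config.panel)
        )
        peak_sets = [RegionSet.read_bed(p, label=f"dataset_{i + 1}")
                     for i, p in enumerate(config.peak_beds)]
        enhancers = (RegionSet.read_bed(config.enhancers, label="enhancers")
                     if config.enhancers else None)
        genes = read_genes(config.genes) if config.genes else []
        interactions = (InteractionTable.read_tsv(config.interactions)
                        if config.interactions else InteractionTable())
        logger.info("load: %d SNPs, %d panel samples, %d peak sets",
                    len(stats), panel.n_samples, len(peak_sets))
        report["stages"]["load"] = {
            "n_snps": len(stats),
            "n_samples": panel.n_samples,
            "input_checksums": {
                "stats": _checksum(config.stats),
                "panel": _checksum(config.panel),
            },
        }

        stage = "consensus"
        peaks = consensus_peaks(peak_sets, config.min_datasets)
        logger.info("consensus: %d peaks from %d sets", len(peaks),
                    len(peak_sets))
        report["stages"]["consensus"] = {
            "n_peaks": len(peaks),
            "covered_bp": peaks.total_span(),
        }

        stage = "clump"
        ccfg = config.clump_config()
        supra = clump(stats, panel, ccfg, tier="supra")
        sub = clump(stats, panel, ccfg, tier="sub")
        logger.info("clump: %d supra, %d sub loci", len(supra), len(sub))
        report["stages"]["clump"] = {
            "n_supra": len(supra),
            "n_sub": len(sub),
            "supra_index_snps": [l.index_snp for l in supra],
        }

        stage = "overlap_tests"
        tests = {}
        for tier_name, loci in (("supra", supra), ("sub", sub)):
            if not loci:
                continue
            scfg = ShuffleConfig(n_iter=config.n_iter, seed=seeds[0])
            tests[f"{tier_name}_overlap"] = locus_shuffle_test(
                loci, peaks, genome, scfg, mode=config.overlap_mode,
            ).to_dict()
            scfg = ShuffleConfig(n_iter=config.n_iter, seed=seeds[1])
            tests[f"{tier_name}_proximity"] = locus_shuffle_test(
                loci, peaks, genome, scfg, mode=config.overlap_mode,
                window=config.proximity_window,
            ).to_dict()
            if enhancers is not None and len(enhancers):
                scfg = ShuffleConfig(n_iter=config.n_iter, seed=seeds[2])
                tests[f"{tier_name}_converse"] = peak_shuffle_test(
                    loci, peaks, enhancers, scfg,
                ).to_dict()
        for name, t in tests.items():
            t.pop("histogram_full", None)
        report["stages"]["overlap_tests"] = tests

        stage = "assign_genes"
        assignment = {
            locus.name: sorted(
                assign_genes(locus, genes, interactions,
                             near_window=config.proximity_window)
            )
            for locus in supra
        }
        assigned_union = sorted({g for v in assignment.values() for g in v})
        report["stages"]["assign_genes"] = {
            "per_locus": assignment,
            "n_assigned": len(assigned_union),
        }

        gsea_result = None
        ranked = None
        if config.counts_condition:
            stage = "rank_table"
            cm = CountMatrix.read_tsv(config.counts_condition,
                                      config.samples_condition)
            ranked = differential_rank_table(
                cm.counts, cm.samples["condition"].to_numpy()
            )
            report["stages"]["rank_table"] = {"n_genes_ranked": len(ranked)}

            stage = "gsea"
            members = frozenset(assigned_union) & {g.gene_id for g in ranked}
            if members:
                gsea_result = gsea_test(
                    ranked, GeneSet("locus-assigned", frozenset(members)),
                    n_perm=config.gsea_n_perm, seed=seeds[3],
                    weight=config.gsea_weight,
                )
                report["stages"]["gsea"] = gsea_result.to_dict()
            else:
                report["stages"]["gsea"] = {"skipped": "no assigned gene in ranked universe"}

        if config.counts_genotype:
            stage = "eqtl"
            cm = CountMatrix.read_tsv(config.counts_genotype,
                                      config.samples_genotype)
            geno = cm.samples["genotype"].to_numpy()
            offsets = np.log(size_factors(cm.counts))
            target_genes = [g for g in assigned_union
                            if g in cm.counts.index][: config.eqtl_max_genes]
            if not target_genes:  # fall back to the most expressed genes
                target_genes = list(
                    cm.counts.sum(axis=1).nlargest(config.eqtl_max_genes).index
                )
            rows = []
            for gid in target_genes:
                res = lrt_genotype(
                    cm.counts.loc[gid].to_numpy(), geno, offsets=offsets,
                    coding=config.eqtl_coding,
                )
                rows.append(
                    {"gene": gid, "beta1": res.beta1,
                     "lrt_stat": res.lrt_stat, "df": res.df,
                     "p": res.p_chi2}
                )
            eqtl = pd.DataFrame(rows)
            report["stages"]["eqtl"] = {
                "n_tested": len(eqtl),
                "n_significant_bonferroni": int(
                    (eqtl["p"] < 0.05 / max(len(eqtl), 1)).sum()
                ),
                "results": eqtl.to_dict(orient="records"),
            }

        if config.counts_paired:
            stage = "paired"
            cm = CountMatrix.read_tsv(config.counts_paired,
                                      config.samples_paired)
            tissue = cm.samples["tissue"].to_numpy()
            pair = cm.samples["pair_id"].to_numpy()
            lv = pd.unique(tissue)
            sf = size_factors(cm.counts)
            norm = cm.counts / sf
            rows = []
            for gid in (assigned_union or list(cm.counts.index[:10])):
                if gid not in norm.index:
                    continue
                a = norm.loc[gid][tissue == lv[0]].to_numpy()
                b = norm.loc[gid][tissue == lv[1]].to_numpy()
                # align by pair id
                pa = pair[tissue == lv[0]]
                pb = pair[tissue == lv[1]]
                order = {p: i for i, p in enumerate(pb)}
                b = b[[order[p] for p in pa]]
                res = paired_test(a, b)
                rows.append({"gene": gid, "p": res.pvalue,
                             "n_pairs": res.n_pairs_used})
            report["stages"]["paired"] = {"results": rows}
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    report["artifacts"] = {
        "loci": [
            {"name": l.name, "tier": l.tier, "chrom": l.chrom,
             "span": [l.span[1], l.span[2]], "index_snp": l.index_snp,
             "pvalue": l.index_pvalue, "n_members": len(l.member_ids)}
            for l in supra + sub
        ],
    }
    out = AnalysisReport(report)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out.to_json(outdir / "report.json")
    return out


def summarize(report: AnalysisReport, outdir=None) -> str:
    """Human-readable summary plus (optionally) null-histogram and
    running-sum figures written to ``outdir``."""
    c = report.content
    lines = [f"pathtune {c['version']} analysis report", ""]
    st = c["stages"]
    if "clump" in st:
        lines.append(
            f"Loci: {st['clump']['n_supra']} supra-threshold, "
            f"{st['clump']['n_sub']} sub-threshold"
        )
    for name, t in st.get("overlap_tests", {}).items():
        lines.append(
            f"  {name}: observed {t['observed']} vs null mean "
            f"{t['null_mean']:.2f} ({t['p_text']}, {t['n_iter']} iterations)"
        )
    if "gsea" in st and "es" in st["gsea"]:
        g = st["gsea"]
        lines.append(
            f"GSEA: ES={g['es']:.3f} NES={g['nes']:.3f} p={g['p_perm']:.4g} "
            f"({g['n_hits']} genes in set)"
        )
    if "eqtl" in st:
        lines.append(
            f"eQTL: {st['eqtl']['n_significant_bonferroni']} of "
            f"{st['eqtl']['n_tested']} genes genotype-associated "
            "(Bonferroni 0.05)"
        )
    text = "\n".join(lines)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _figures(report, outdir)
        (outdir / "summary.txt").write_text(text + "\n")
    return text


def _figures(report: AnalysisReport, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    st = report.content["stages"]
    for name, t in st.get("overlap_tests", {}).items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        hist = {int(k): v for k, v in t["histogram"].items()}
        xs = np.arange(0, max(max(hist), t["observed"]) + 2)
        ax.bar(xs, [hist.get(int(x), 0) for x in xs], color="steelblue")
        ax.axvline(t["observed"], color="red", lw=2)
        ax.annotate("observed", (t["observed"], ax.get_ylim()[1] * 0.9),
                    color="red", ha="left")
        ax.set_xlabel("overlap count")
        ax.set_ylabel("iterations")
        ax.set_title(f"{name}: {t['p_text']}")
        fig.tight_layout()
        fig.savefig(outdir / f"null_{name}.svg")
        plt.close(fig)
    g = st.get("gsea", {})
    if "running_sum" in g:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(g["running_sum"], color="green")
        ax.axhline(0, color="grey", lw=0.5)
        for r in g["hit_ranks"]:
            ax.axvline(r, color="black", ymin=0.0, ymax=0.05, lw=0.5)
        ax.set_xlabel("rank")
        ax.set_ylabel("running enrichment score")
        ax.set_title(f"ES={g['es']:.2f} NES={g['nes']:.2f} p={g['p_perm']:.3g}")
        fig.tight_layout()
        fig.savefig(outdir / "gsea_running_sum.svg")
        plt.close(fig)
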