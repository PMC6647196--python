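"""End-to-end orchestration: simulate -> scan -> refine -> express -> consequence -> report.

Each stage writes its outputs under ``out_dir/<stage>/`` and contributes to
a JSON run manifest (parameters, seeds, input digests, key results). All
randomness flows from the run seed, so rerunning with the same
configuration reproduces identical outputs.

The simulate/scan stages operate on the compressed-genome scale (the
simulated chromosome stands in for a whole-genome scan), while the refine
stage simulates its own backcross population at a fine-mapping physical
map density around the scan region — mirroring how pooled scans and
recombinant genotyping address different physical scales.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consequence as cq
from . import expression as xp
from .intervals import GenomicInterval, write_bed
from .refine import (
    GeneModel,
    MarkerLocus,
    genes_in_interval,
    narrow_by_recombinants,
    rank_candidates,
)
from .scan import plot_scan, scan_sites
from .simulate import SimulationConfig, make_pools, simulate_expression, simulate_pool_depths, simulate_population
from .variants import VariantSite, read_vcf, write_vcf

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("simulate", "scan", "refine", "express", "consequence", "report")

_CODON_POOL = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """Per-stage parameter blocks for one reproducible run."""

    seed: int = 0
    stages: tuple = ALL_STAGES
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    scan: dict = field(default_factory=dict)  # window, ed_power, merge_gap, by_class, ...
    refine: dict = field(default_factory=dict)  # n_markers, n_individuals, cm_per_mb, margin
    express: dict = field(default_factory=dict)  # n_background_genes, lfc, dispersion, reps
    consequence: dict = field(default_factory=dict)  # promoter_window, cds_codons
    inputs: dict = field(default_factory=dict)  # external paths for partial runs
    plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.stages = tuple(cfg.stages)
        return cfg


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _genotype_codes(dosages: np.ndarray) -> np.ndarray:
    return np.array(["A", "H", "B"], dtype=object)[dosages]


def _synthetic_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_CODON_POOL, size=n_codons - 2)
    return "ATG" + "".join(codons) + "TAA"


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "simulate": dict(config.simulate),
            "scan": dict(config.scan),
            "refine": dict(config.refine),
            "express": dict(config.express),
            "consequence": dict(config.consequence),
        },
        "inputs": {},
        "outputs": {},
        "results": {},
    }

    sites: list[VariantSite] | None = None
    sim_cfg: SimulationConfig | None = None
    scan_regions: list[GenomicInterval] = []
    narrowed: GenomicInterval | None = None
    interval_genes: list[GeneModel] = []
    causal_gene: GeneModel | None = None
    deg_flags: dict[str, bool] = {}
    evidence: dict[str, list] = {}

    if "simulate" in config.stages:
        stage_dir = out / "simulate"
        stage_dir.mkdir(exist_ok=True)
        try:
            sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
            pop = simulate_population(sim_cfg)
            pools = make_pools(pop, sim_cfg.pool_size, seed=config.seed)
            sites = simulate_pool_depths(pop, pools, sim_cfg)
            vcf_path = stage_dir / "pools.vcf"
            write_vcf(sites, vcf_path, contig_length=sim_cfg.chrom_length)
            truth = {
                "causal_pos": sim_cfg.causal_pos,
                "chrom": sim_cfg.chrom,
                "n_fuzzless": int(pop.is_fuzzless.sum()),
                "n_fuzzy": int((~pop.is_fuzzless).sum()),
            }
            (stage_dir / "truth.json").write_text(json.dumps(truth, indent=2))
            manifest["outputs"]["simulate"] = {
                "vcf": str(vcf_path),
                "truth": str(stage_dir / "truth.json"),
            }
            manifest["results"]["simulate"] = truth
            manifest["parameters"]["simulate"] = asdict(sim_cfg)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError("simulate", str(exc)) from exc

    if "scan" in config.stages:
        stage_dir = out / "scan"
        stage_dir.mkdir(exist_ok=True)
        try:
            if sites is None:
                vcf_in = config.inputs.get("vcf")
                if vcf_in is None:
                    raise ValueError("scan without simulate requires inputs['vcf']")
                manifest["inputs"]["vcf"] = {"path": str(vcf_in), "sha256": _sha256(vcf_in)}
                sites = read_vcf(vcf_in)
            result = scan_sites(sites, **config.scan)
            scan_regions = result.intersected
            for key, track in result.tracks.items():
                name = key.replace("/", "_")
                pd.DataFrame(
                    {
                        "chrom": track.chrom,
                        "pos": track.positions.astype(np.int64),
                        "raw": track.raw,
                        "fitted": track.fitted,
                    }
                ).to_csv(stage_dir / f"track_{name}.tsv", sep="\t", index=False)
            write_bed(scan_regions, stage_dir / "candidate_regions.bed")
            summary = {
                "thresholds": {k: float(v) for k, v in result.thresholds.items()},
                "regions": {
                    k: [[iv.chrom, iv.start, iv.end] for iv in r]
                    for k, r in result.regions.items()
                },
                "intersected": [[iv.chrom, iv.start, iv.end] for iv in scan_regions],
                "seed": config.seed,
                "settings": dict(config.scan),
            }
            (stage_dir / "summary.json").write_text(json.dumps(summary, indent=2))
            if config.plot:
                plot_scan(result, stage_dir / "scan.png")
            manifest["outputs"]["scan"] = {
                "regions_bed": str(stage_dir / "candidate_regions.bed"),
                "summary": str(stage_dir / "summary.json"),
            }
            manifest["results"]["scan"] = summary
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("scan", str(exc)) from exc

    if "refine" in config.stages:
        stage_dir = out / "refine"
        stage_dir.mkdir(exist_ok=True)
        try:
            if not scan_regions:
                raise ValueError("refine requires a non-empty scan candidate region")
            base = sim_cfg or SimulationConfig(seed=config.seed, **config.simulate)
            region = max(scan_regions, key=lambda iv: iv.length)
            p = {
                "n_markers": 17,
                "n_individuals": 607,
                "cm_per_mb": 2.0,
                "margin": 50_000,
                "n_genes": 7,
                **config.refine,
            }
            ref_cfg = replace(
                base,
                cross_type="BC1",
                n_individuals=p["n_individuals"],
                cm_per_mb=p["cm_per_mb"],
                pool_size=0,
                seed=config.seed + 1,
            )
            ref_pop = simulate_population(ref_cfg)
            lo = max(1, region.start - p["margin"])
            hi = min(base.chrom_length, region.end + p["margin"])
            positions = np.unique(
                np.round(np.linspace(lo, hi, p["n_markers"])).astype(np.int64)
            )
            markers = [
                MarkerLocus(name=f"M{i + 1}", chrom=base.chrom, position=int(pos))
                for i, pos in enumerate(positions)
            ]
            dosages = ref_pop.dosages(positions.astype(float))
            geno = pd.DataFrame(
                _genotype_codes(dosages),
                columns=[m.name for m in markers],
                index=[f"ind{i}" for i in range(ref_pop.n_individuals)],
            )
            res = narrow_by_recombinants(markers, geno, ref_pop.phenotypes)
            narrowed = res.interval
            # synthetic gene models tiling the narrowed interval, one over the locus
            rng = np.random.default_rng([config.seed, 7])
            span = max(narrowed.length, p["n_genes"] * 3000)
            g_len = max(600, span // (3 * p["n_genes"]))
            starts = np.linspace(narrowed.start, narrowed.end - g_len, p["n_genes"])
            starts = np.round(starts).astype(np.int64)
            causal_pos = base.causal_pos
            # shift the nearest gene so that it contains the causal position
            nearest = int(np.argmin(np.abs(starts + g_len / 2 - causal_pos)))
            starts[nearest] = min(max(narrowed.start, causal_pos - g_len // 2),
                                  max(narrowed.start, narrowed.end - g_len))
            interval_genes = [
                GeneModel(
                    gene_id=f"GENE{i + 1:02d}",
                    chrom=base.chrom,
                    start=int(s),
                    end=int(s + g_len),
                    strand="+" if rng.random() < 0.5 else "-",
                    cds_length=int(g_len // 2),
                )
                for i, s in enumerate(starts)
            ]
            causal_gene = next(
                (g for g in interval_genes if g.start <= causal_pos <= g.end), None
            )
            geno_path = stage_dir / "genotypes.tsv"
            geno.assign(phenotype=ref_pop.phenotypes).to_csv(geno_path, sep="\t")
            write_bed([narrowed], stage_dir / "narrowed_interval.bed")
            genes_df = pd.DataFrame([asdict(g) for g in interval_genes])
            genes_df.to_csv(stage_dir / "genes.tsv", sep="\t", index=False)
            info = {
                "interval": [narrowed.chrom, narrowed.start, narrowed.end],
                "flanking_markers": [res.left_marker.name, res.right_marker.name],
                "n_double_crossover_flags": res.n_double_crossover_flags,
                "causal_gene": causal_gene.gene_id if causal_gene else None,
                "n_genes": len(genes_in_interval(interval_genes, narrowed)),
            }
            (stage_dir / "refine.json").write_text(json.dumps(info, indent=2))
            manifest["outputs"]["refine"] = {
                "interval_bed": str(stage_dir / "narrowed_interval.bed"),
                "genes": str(stage_dir / "genes.tsv"),
                "genotypes": str(geno_path),
            }
            manifest["results"]["refine"] = info
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("refine", str(exc)) from exc

    if "express" in config.stages:
        stage_dir = out / "express"
        stage_dir.mkdir(exist_ok=True)
        try:
            p = {
                "n_background_genes": 493,
                "n_true_deg": 30,
                "lfc": 5.0,
                "dispersion": 0.001,
                "reps": 2,
                "mean_expression": 2000.0,
                "sigma_log": 0.8,
                "library_size": 10_000_000,
                **config.express,
            }
            n_genes = p["n_background_genes"] + len(interval_genes)
            sim = simulate_expression(
                n_genes=n_genes,
                n_true_deg=p["n_true_deg"],
                lfc=p["lfc"],
                dispersion=p["dispersion"],
                reps=p["reps"],
                mean_expression=p["mean_expression"],
                sigma_log=p["sigma_log"],
                library_size=p["library_size"],
                seed=config.seed + 2,
            )
            # relabel simulated genes so the causal gene is a strongly
            # expressed up-regulated true DEG and the other interval genes
            # are background (null) genes
            stage1_truth = sorted(sim.truth.get(1, set()))
            null_genes = sorted(set(sim.counts.index) - set(stage1_truth))
            mapping = {}
            others = [g for g in interval_genes if causal_gene and g.gene_id != causal_gene.gene_id]
            if causal_gene is not None and stage1_truth:
                up = [g for g in stage1_truth if sim.direction[g] > 0] or stage1_truth
                causal_row = sim.counts.loc[up].mean(axis=1).idxmax()
                mapping[causal_row] = causal_gene.gene_id
            for old, g in zip(null_genes, others):
                mapping[old] = g.gene_id
            counts = sim.counts.rename(index=mapping)
            lengths = sim.lengths.rename(index=mapping)
            xp.write_expression_tsv(counts, lengths, stage_dir / "expression.tsv")
            manifest["inputs"]["expression"] = {
                "path": str(stage_dir / "expression.tsv"),
                "sha256": _sha256(stage_dir / "expression.tsv"),
            }
            diff = xp.run_differential(counts, lengths, library_totals=sim.library_totals)
            diff.to_csv(stage_dir / "differential.tsv", sep="\t", index=False)
            deg_sets = {
                f"{stage}DPA": set(sub.loc[sub["significant"], "gene_id"])
                for stage, sub in diff.groupby("stage")
            }
            venn = xp.venn_partition(deg_sets)
            venn_json = {"&".join(k): v for k, v in venn.items()}
            (stage_dir / "venn.json").write_text(json.dumps(venn_json, indent=2))
            deg_flags = {
                g.gene_id: any(g.gene_id in s for s in deg_sets.values())
                for g in interval_genes
            }
            manifest["outputs"]["express"] = {
                "differential": str(stage_dir / "differential.tsv"),
                "venn": str(stage_dir / "venn.json"),
            }
            manifest["results"]["express"] = {
                "n_deg_per_stage": {k: len(v) for k, v in deg_sets.items()},
                "interval_deg": sorted(g for g, f in deg_flags.items() if f),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("express", str(exc)) from exc

    if "consequence" in config.stages:
        stage_dir = out / "consequence"
        stage_dir.mkdir(exist_ok=True)
        try:
            p = {"promoter_window": 2000, "cds_codons": 87, **config.consequence}
            rng = np.random.default_rng([config.seed, 8])
            records = []
            if causal_gene is not None:
                cds = _synthetic_cds(rng, p["cds_codons"])
                boundary = 3 * int(rng.integers(1, p["cds_codons"] - 1)) + 1
                ins = cq.classify_coding_insertion(
                    cds, boundary, "TTG", gene_id=causal_gene.gene_id
                )
                records.append(ins)
                if causal_gene.strand == "+":
                    prom_pos = [causal_gene.start - 500, causal_gene.start - 1200]
                else:
                    prom_pos = [causal_gene.end + 500, causal_gene.end + 1200]
                prom_sites = [
                    VariantSite(causal_gene.chrom, int(prom_pos[0]), "G", "A"),
                    VariantSite(causal_gene.chrom, int(prom_pos[1]), "C", "A"),
                ]
                records.extend(
                    cq.promoter_variants(
                        prom_sites, causal_gene, upstream_window=p["promoter_window"]
                    )
                )
                evidence = {causal_gene.gene_id: records}
            pd.DataFrame([asdict(r) for r in records]).to_csv(
                stage_dir / "consequences.tsv", sep="\t", index=False
            )
            manifest["outputs"]["consequence"] = {
                "table": str(stage_dir / "consequences.tsv")
            }
            manifest["results"]["consequence"] = {
                "n_records": len(records),
                "frame_effects": [r.frame_effect for r in records],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("consequence", str(exc)) from exc

    if "report" in config.stages:
        stage_dir = out / "report"
        stage_dir.mkdir(exist_ok=True)
        try:
            if not interval_genes:
                raise ValueError("report requires the refine stage's gene models")
            report = rank_candidates(interval_genes, deg_flags, evidence)
            report.to_csv(stage_dir / "candidates.tsv", sep="\t", index=False)
            tier1 = report.loc[report["tier"] == 1, "gene_id"].tolist()
            manifest["outputs"]["report"] = {"candidates": str(stage_dir / "candidates.tsv")}
            manifest["results"]["report"] = {
                "tier1": tier1,
                "causal_gene": causal_gene.gene_id if causal_gene else None,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("report", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
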