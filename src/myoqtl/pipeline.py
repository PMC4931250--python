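"""Pipeline orchestration: run each analysis stage over an artefact directory.

Every stage reads its inputs from, and writes its outputs to, one artefact
directory using the formats in :mod:`myoqtl.io_`, so stages can be run
individually (via the CLI subcommands) or end-to-end with
:func:`run_pipeline`. Each stage drops a YAML manifest capturing the
effective configuration and seed; rerunning a stage with the same inputs,
config and seed reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import eqtl as eqtl_mod
from . import io_
from . import regulatory as reg_mod
from . import trait_assoc as ta
from .datatypes import ChromatinSegmentation
from .sim import SimConfig, simulate_study
from .specificity import TissueExpressionPanel, score_panel

log = logging.getLogger("myoqtl")


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    ``sim`` holds overrides for :class:`SimConfig`; the demo defaults below
    are deliberately smaller than the study-scale simulator defaults so a
    full run finishes in about a minute.
    """

    outdir: str = "myoqtl_run"
    seed: int = 0
    sim: dict = field(
        default_factory=lambda: {
            "n_samples": 150,
            "n_genes": 300,
            "n_variants": 4000,
            "frac_eqtl_genes": 0.5,
        }
    )
    target_tissue: str = "skeletal_muscle"
    window_bp: int = 1_000_000
    mac_min: int = 5
    factors_k: int = 60
    stop_p: float = 0.0019
    fdr: str = "bh"
    n_gwas_snps: int = 8
    min_samples: int = 10
    downsample_cov: int = 30
    coverage_pct: float = 75.0
    two_sided_method: str = "minlike"
    fracref_bounds: tuple = (0.01, 0.99)
    stretch_min_bp: int = 3_000
    typical_max_bp: int = 800
    stretch_quantile: float | None = None
    n_null_sets: int = 200
    min_pool: int = 50
    threads: int = 1
    force: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fracref_bounds"] = list(self.fracref_bounds)
        return d


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: RunConfig) -> Path:
    """Generate every pipeline input with planted truth; write all files."""
    out = _outdir(config)
    sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
    study = simulate_study(sim_cfg)
    io_.write_vcf(study.genotypes, out / "genotypes.vcf")
    io_.write_matrix_tsv(study.expression, out / "expression.tsv")
    io_.write_matrix_tsv(study.panel.x, out / "tissue_panel.tsv")
    io_.write_table(study.covariates.reset_index(), out / "covariates.tsv")
    io_.write_table(study.phenotypes.reset_index(), out / "phenotypes.tsv")
    io_.write_table(study.gene_lengths, out / "gene_lengths.tsv")
    io_.write_table(study.go_memberships, out / "go_memberships.tsv")
    io_.write_table(study.allele_counts, out / "allele_counts.tsv")
    io_.write_table(study.ase_mask, out / "ase_mask.tsv")
    io_.write_gene_annotation(study.genes, out / "genes.tsv")
    for seg in study.segmentations:
        io_.write_bed_states(seg, out / f"chromatin_{seg.tissue_id}.bed")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name in (
        "eqtl_truth",
        "ase_truth",
        "specific_gene_truth",
        "enhancer_truth",
        "de_truth",
        "go_truth",
        "bias_snp_truth",
    ):
        io_.write_table(getattr(study.truth, name), truth_dir / f"{name}.tsv")
    # GWAS list: planted eQTL variants plus a few nulls, labelled by trait
    truth = study.truth.eqtl_truth
    nonzero = truth[truth["beta_std"] != 0]
    k = min(config.n_gwas_snps, len(nonzero))
    gwas = nonzero.sample(n=k, random_state=config.seed)[
        ["variant_id", "gene_id"]
    ].copy()
    gwas["trait"] = "t2d"
    io_.write_table(
        gwas.rename(columns={"variant_id": "gwas_variant_id"}), out / "gwas_snps.tsv"
    )
    io_.write_manifest(
        out / "manifest_simulate.yaml", config.to_dict(), config.seed
    )
    return out


def stage_specificity(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    panel = TissueExpressionPanel(
        x=io_.read_matrix_tsv(out / "tissue_panel.tsv"),
        target_tissue=config.target_tissue,
    )
    scores = score_panel(panel)
    io_.write_table(scores.reset_index(), out / "specificity_scores.tsv")
    return scores


def stage_trait_assoc(config: RunConfig) -> dict[str, pd.DataFrame]:
    out = _outdir(config)
    rng = np.random.default_rng(config.seed + 1)
    expr = io_.read_matrix_tsv(out / "expression.tsv")
    cov = io_.read_table(out / "covariates.tsv").set_index("sample_id")
    phen = io_.read_table(out / "phenotypes.tsv").set_index("sample_id")
    lengths = io_.read_table(out / "gene_lengths.tsv").set_index("gene_id")
    members = io_.read_table(out / "go_memberships.tsv")

    results: dict[str, pd.DataFrame] = {}
    go_results: dict[str, pd.DataFrame] = {}
    log_len = np.log10(lengths["length_bp"]).reindex(expr.index)

    y_single = ta.transform_expression(expr, rng=rng, double=False)
    results["t2d"] = ta.t2d_association(
        y_single, phen["t2d"].to_numpy(), cov, fdr_method=config.fdr
    )
    y_double = ta.transform_expression(expr, cov, rng=rng, double=True)
    for trait in [c for c in phen.columns if c != "t2d"]:
        x = ta.transform_trait(phen[trait].to_numpy(), cov, rng=rng)
        results[trait] = ta.quant_trait_association(
            y_double, x, fdr_method=config.fdr
        )
    for trait, res in results.items():
        io_.write_table(
            res.reset_index(names="gene_id"), out / f"assoc_{trait}.tsv"
        )
        go_results[trait] = ta.go_enrichment(
            ta.signed_logp(res), log_len, members, fdr_method=config.fdr
        )
        io_.write_table(
            go_results[trait].reset_index(), out / f"go_{trait}.tsv"
        )
    presented = ta.present_go_terms(go_results, members)
    io_.write_table(presented, out / "go_presented.tsv")
    io_.write_manifest(out / "manifest_trait_assoc.yaml", config.to_dict(), config.seed)
    return results


def _load_genotypes(out: Path, force: bool = False):
    gm, report = io_.read_vcf(out / "genotypes.vcf")
    if report.n_rejected:
        if not force:
            raise ValueError(
                "refusing to proceed with rejected records (use --force):\n"
                + report.notes()
            )
        log.warning("VCF validation: %s", report.notes())
    return gm


def stage_eqtl(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    gm = _load_genotypes(out, config.force)
    expr = io_.read_matrix_tsv(out / "expression.tsv")
    cov = io_.read_table(out / "covariates.tsv").set_index("sample_id")
    genes = io_.read_gene_annotation(out / "genes.tsv")
    k = min(config.factors_k, expr.shape[1] // 4)
    y = eqtl_mod.latent_factor_adjust(
        expr, cov, k, rng=np.random.default_rng(config.seed + 2)
    )
    pairs = eqtl_mod.cis_pairs(genes, gm, config.window_bp)
    records = eqtl_mod.map_cis_eqtl(
        y, gm, pairs, mac_min=config.mac_min, fdr_method=config.fdr
    )
    io_.write_table(records, out / "eqtl_full.tsv")
    signif = records[records["q"] <= 0.05]
    pruned = eqtl_mod.ld_prune_per_gene(signif, gm)
    io_.write_table(pruned, out / "eqtl_pruned.tsv")
    best = eqtl_mod.best_per_gene(signif, gm)
    io_.write_table(best, out / "eqtl_best_per_gene.tsv")
    io_.write_matrix_tsv(y, out / "expression_adjusted.tsv")
    io_.write_manifest(out / "manifest_eqtl.yaml", config.to_dict(), config.seed)
    return records


def stage_conditional(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    gm = _load_genotypes(out, config.force)
    genes = io_.read_gene_annotation(out / "genes.tsv")
    y = io_.read_matrix_tsv(out / "expression_adjusted.tsv")
    gwas = io_.read_table(out / "gwas_snps.tsv")
    res = eqtl_mod.conditional_analysis(
        gwas, y, gm, genes, stop_p=config.stop_p,
        window_bp=config.window_bp, fdr_method=config.fdr,
    )
    io_.write_table(res, out / "conditional_results.tsv")
    io_.write_manifest(out / "manifest_conditional.yaml", config.to_dict(), config.seed)
    return res


def stage_ase(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    counts = io_.read_table(out / "allele_counts.tsv")
    mask = io_.read_table(out / "ase_mask.tsv")
    per_sample, combined = ase_mod.run_ase(
        counts,
        mask,
        min_samples=config.min_samples,
        downsample_cov=config.downsample_cov,
        pct=config.coverage_pct,
        method=config.two_sided_method,
        seed=config.seed + 3,
    )
    io_.write_table(per_sample, out / "ase_per_sample.tsv")
    io_.write_table(combined, out / "ase_combined.tsv")
    io_.write_manifest(out / "manifest_ase.yaml", config.to_dict(), config.seed)
    return combined


def stage_enhancers(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    target = f"chromatin_target_tissue.bed"
    seg, _ = io_.read_bed_states(out / target, tissue_id="target_tissue")
    others = []
    for p in sorted(out.glob("chromatin_other_tissue_*.bed")):
        other_seg, _ = io_.read_bed_states(p, tissue_id=p.stem)
        others.append(other_seg)
    runs = reg_mod.merge_enhancer_runs(seg)
    classified = reg_mod.classify_enhancers(
        runs, config.stretch_min_bp, config.typical_max_bp,
        stretch_quantile=config.stretch_quantile,
    )
    if others:
        classified = reg_mod.tissue_specific_filter(classified, others)
    io_.write_table(classified, out / "enhancers.tsv")
    bed = classified.copy()
    bed["name"] = bed["class"]
    bed[["chrom", "start", "end", "name"]].to_csv(
        out / "enhancers.bed", sep="\t", header=False, index=False
    )
    io_.write_manifest(out / "manifest_enhancers.yaml", config.to_dict(), config.seed)
    return classified


def stage_enrichment(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    gm = _load_genotypes(out, config.force)
    genes = io_.read_gene_annotation(out / "genes.tsv")
    best = io_.read_table(out / "eqtl_best_per_gene.tsv")
    scores = io_.read_table(out / "specificity_scores.tsv").set_index("gene_id")
    enhancers = io_.read_table(out / "enhancers.tsv")
    universe = reg_mod.annotate_universe(gm, genes)
    feature_sets = {
        cls: enhancers[enhancers["class"] == cls][["chrom", "start", "end"]]
        for cls in ("stretch", "typical")
    }
    result = reg_mod.stratified_enrichment(
        best,
        scores["decile"],
        feature_sets,
        universe,
        n_null_sets=config.n_null_sets,
        min_pool=config.min_pool,
        seed=config.seed + 4,
    )
    io_.write_table(result, out / "enrichment.tsv")
    io_.write_manifest(out / "manifest_enrichment.yaml", config.to_dict(), config.seed)
    return result


STAGES = (
    ("simulate", stage_simulate),
    ("specificity", stage_specificity),
    ("trait_assoc", stage_trait_assoc),
    ("eqtl", stage_eqtl),
    ("conditional", stage_conditional),
    ("ase", stage_ase),
    ("enhancers", stage_enhancers),
    ("enrichment", stage_enrichment),
)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in dependency order; halt on the failing stage."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = _outdir(config)
    for name, fn in STAGES:
        log.info("stage %s", name)
        try:
            fn(config)
        except Exception:
            log.error("stage %s failed", name)
            raise
    return out
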