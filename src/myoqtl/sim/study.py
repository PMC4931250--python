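"""Top-level orchestration: simulate every pipeline input with planted truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import ChromatinSegmentation, GeneAnnotation, GenotypeMatrix
from ..specificity import TissueExpressionPanel, score_panel
from .allele_counts import simulate_allele_counts
from .chromatin import simulate_chromatin
from .config import SimConfig, TruthTables
from .expression import simulate_expression, simulate_genes
from .genotypes import simulate_genotypes
from .panel import simulate_tissue_panel
from .phenotypes import simulate_phenotypes


@dataclass
class SimulatedStudy:
    """Every input the pipeline consumes, plus the planted-truth registries."""

    config: SimConfig
    genotypes: GenotypeMatrix
    genes: GeneAnnotation
    panel: TissueExpressionPanel
    expression: pd.DataFrame  # FPKM-like, trait effects planted
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    gene_lengths: pd.DataFrame
    go_memberships: pd.DataFrame
    allele_counts: pd.DataFrame
    ase_mask: pd.DataFrame
    segmentations: list[ChromatinSegmentation]
    specificity_scores: pd.DataFrame
    truth: TruthTables


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every generator under one seed; stage seeds are spawned so each
    stage is individually reproducible."""
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]

    genotypes = simulate_genotypes(config, rngs[0])
    panel, specific_truth = simulate_tissue_panel(config, rngs[1])
    genes = simulate_genes(genotypes, config, rngs[2])
    expression0, covariates, eqtl_truth = simulate_expression(
        genotypes, genes, config, rngs[2]
    )
    (
        phenotypes,
        expression,
        gene_lengths,
        go_memberships,
        de_truth,
        go_truth,
    ) = simulate_phenotypes(expression0, covariates, config, rngs[3])
    counts, mask, ase_truth, bias_truth = simulate_allele_counts(
        genotypes, config, rngs[4]
    )
    scores = score_panel(panel)
    segmentations, enhancer_truth = simulate_chromatin(
        genes, genotypes, eqtl_truth, scores["decile"], config, rngs[5]
    )
    truth = TruthTables(
        eqtl_truth=eqtl_truth,
        ase_truth=ase_truth,
        specific_gene_truth=specific_truth,
        enhancer_truth=enhancer_truth,
        de_truth=de_truth,
        go_truth=go_truth,
        bias_snp_truth=bias_truth,
    )
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        genes=genes,
        panel=panel,
        expression=expression,
        covariates=covariates,
        phenotypes=phenotypes,
        gene_lengths=gene_lengths,
        go_memberships=go_memberships,
        allele_counts=counts,
        ase_mask=mask,
        segmentations=segmentations,
        specificity_scores=scores,
        truth=truth,
    )
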