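"""Simulation configuration and planted-truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults mirror the study design the package targets: 271 phenotyped
    samples of which 267 are genotyped, a 16-tissue reference expression
    panel, block-structured LD, negative-binomial allelic coverage, and
    planted effects for every downstream recovery analysis.
    """

    n_samples: int = 267
    n_genes: int = 2000
    n_variants: int = 20000
    n_tissues: int = 16
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 50
    ld_decay: float = 0.9
    frac_specific_genes: float = 0.05
    eqtl_effect_sizes: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0)
    frac_eqtl_genes: float = 0.5  # genes assigned a (possibly zero) planted effect
    ase_effect_fracrefs: tuple[float, ...] = (0.7,)
    frac_ase_sites: float = 0.05  # variants that are transcribed heterozygous sites
    frac_ase_effects: float = 0.2  # of ASE sites, fraction with planted imbalance
    frac_bias_snps: float = 0.05  # of ASE sites, fraction with planted mapping bias
    coverage_mean: float = 50.0
    coverage_dispersion: float = 0.3
    n_latent_factors: int = 3
    batch_levels: int = 3
    # genome layout
    variant_spacing_bp: int = 2000
    blocks_per_chrom: int = 10
    # trait / GO structure
    n_quant_traits: int = 3
    frac_de_genes: float = 0.02
    de_effect_size: float = 0.8
    length_confound: float = 0.0  # directional length-coupled trait effect
    n_go_terms: int = 50
    # chromatin structure
    stretch_target_fold: float = 3.0
    stretch_background_coverage: float = 0.02
    typical_background_coverage: float = 0.01
    n_other_tissues: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_variants": self.n_variants,
            "n_tissues": self.n_tissues,
            "ld_block_size": self.ld_block_size,
            "batch_levels": self.batch_levels,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        for name in (
            "frac_specific_genes",
            "frac_eqtl_genes",
            "frac_ase_sites",
            "frac_ase_effects",
            "frac_bias_snps",
            "frac_de_genes",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        for f in self.ase_effect_fracrefs:
            if not (0 < f < 1):
                raise ValueError("ase_effect_fracrefs must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["eqtl_effect_sizes"] = list(self.eqtl_effect_sizes)
        d["ase_effect_fracrefs"] = list(self.ase_effect_fracrefs)
        return d


@dataclass
class TruthTables:
    """Planted-effect registries emitted by the simulator.

    Every DataFrame is written/read losslessly as TSV; downstream recovery
    tests compare pipeline estimates against these tables.
    """

    eqtl_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    ase_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    specific_gene_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    enhancer_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    de_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    go_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    bias_snp_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
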