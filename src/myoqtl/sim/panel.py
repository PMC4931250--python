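"""Multi-tissue reference expression panel with planted target-specific genes.

Background genes receive a gene-level baseline (log-normal, FPKM-like) spread
near-uniformly across tissues, so their across-tissue entropy sits near
``log2(n_tissues)`` bits. Planted specific genes concentrate >= 90% of their
panel expression in the target tissue and draw higher baselines, placing them
in the top specificity decile by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..specificity import TissueExpressionPanel
from .config import SimConfig

TARGET_TISSUE = "skeletal_muscle"

_OTHER_TISSUES = (
    "adipose",
    "adrenal",
    "brain",
    "breast",
    "colon",
    "heart",
    "kidney",
    "liver",
    "lung",
    "lymph_node",
    "ovary",
    "prostate",
    "testis",
    "thyroid",
    "white_blood_cells",
)


def tissue_names(n_tissues: int) -> list[str]:
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    others = [
        _OTHER_TISSUES[i % len(_OTHER_TISSUES)]
        + ("" if i < len(_OTHER_TISSUES) else f"_{i // len(_OTHER_TISSUES)}")
        for i in range(n_tissues - 1)
    ]
    return [TARGET_TISSUE] + others


def simulate_tissue_panel(
    config: SimConfig, rng: np.random.Generator
) -> tuple[TissueExpressionPanel, pd.DataFrame]:
    """Return the gene x tissue panel and the specific-gene truth table."""
    if config.n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    g, t = config.n_genes, config.n_tissues
    genes = [f"G{i:05d}" for i in range(g)]
    tissues = tissue_names(t)

    n_specific = int(round(config.frac_specific_genes * g))
    specific_idx = rng.choice(g, size=n_specific, replace=False)
    specific_mask = np.zeros(g, dtype=bool)
    specific_mask[specific_idx] = True

    base = rng.lognormal(mean=1.0, sigma=1.0, size=g)  # FPKM-like baselines
    x = base[:, None] * rng.uniform(0.8, 1.25, size=(g, t))

    # planted specific genes: high baseline, target share drawn in [0.92, 0.98]
    share = rng.uniform(0.92, 0.98, size=n_specific)
    hi_base = rng.lognormal(mean=3.0, sigma=0.5, size=n_specific)
    off = rng.uniform(0.8, 1.25, size=(n_specific, t - 1))
    off_total = off.sum(axis=1)
    x[specific_idx, 1:] = off * hi_base[:, None]
    x[specific_idx, 0] = share / (1 - share) * off_total * hi_base

    panel = TissueExpressionPanel(
        x=pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=tissues),
        target_tissue=TARGET_TISSUE,
    )
    truth = pd.DataFrame(
        {"gene_id": np.array(genes)[specific_mask], "target_tissue": TARGET_TISSUE}
    )
    return panel, truth
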