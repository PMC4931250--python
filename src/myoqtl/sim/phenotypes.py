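"""Phenotype, differential-expression and GO-term simulation.

Disease status (0/1, emulating normal glucose tolerance vs T2D) and
quantitative traits (fasting glucose / fasting insulin / BMI analogues) are
drawn independently of expression; planted trait effects are then ADDED to
the expression of the chosen differentially-expressed genes (``expression_out
= expression + beta * trait``), which is the generative direction matching a
regression of expression on trait.

GO terms are random gene sets; a planted positive (negative) term is seeded
with genes differentially expressed up (down) with disease status. Gene
lengths are log-normal, and an optional directional length-coupled trait
effect (``length_confound > 0``) makes longer genes systematically more
disease-associated, creating a long-gene null term that looks enriched
unless the enrichment model adjusts for gene length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

QUANT_TRAITS = ("fasting_glucose", "fasting_insulin", "bmi")


def simulate_phenotypes(
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[
    pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame
]:
    """Simulate phenotypes and plant trait effects into expression.

    Returns ``(phenotypes, expression_out, gene_lengths, go_memberships,
    de_truth, go_truth)``.
    ``expression`` is expected on the FPKM-like positive scale; effects are
    planted on its log scale.
    """
    samples = expression.columns
    n = len(samples)
    if not samples.equals(covariates.index):
        raise ValueError("expression and covariate samples do not match")
    genes = expression.index.to_numpy()
    g = len(genes)

    status = rng.integers(0, 2, size=n)  # balanced case/control
    quant = {
        t: rng.normal(0, 1, size=n) for t in QUANT_TRAITS[: config.n_quant_traits]
    }
    phenotypes = pd.DataFrame({"t2d": status, **quant}, index=samples)
    phenotypes.index.name = "sample_id"

    logx = np.log(expression.to_numpy() + 1e-9)
    t_std = (status - status.mean()) / (status.std() or 1.0)

    # planted DE genes: half up, half down with disease status
    n_de = int(round(config.frac_de_genes * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    de_beta = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0) * config.de_effect_size
    de_rows = []
    for idx, b in zip(de_idx, de_beta):
        logx[idx] += b * t_std
        de_rows.append({"gene_id": genes[idx], "trait": "t2d", "beta": b})

    # gene lengths; optional directional length-coupled disease effect
    lengths = np.exp(rng.normal(np.log(20_000), 0.8, size=g)).round().astype(int)
    log_len = np.log10(lengths)
    if config.length_confound > 0:
        z = (log_len - log_len.mean()) / log_len.std()
        logx += (config.length_confound * z)[:, None] * t_std[None, :]
    gene_lengths = pd.DataFrame({"gene_id": genes, "length_bp": lengths})

    # GO terms
    up = set(de_idx[de_beta > 0])
    down = set(de_idx[de_beta < 0])
    # long-gene null term: membership probability log-linear in gene length
    # (the same functional form the enrichment model adjusts for), excluding
    # genes with true trait effects
    z_len = (log_len - log_len.mean()) / log_len.std()
    w = np.exp(2.0 * z_len)
    w[list(up | down)] = 0.0
    w /= w.sum()
    term_rows = []
    go_truth_rows = []
    n_terms = config.n_go_terms
    for t in range(n_terms):
        term_id = f"GO:{t:07d}"
        if t == 0 and up:
            members = list(up) + list(
                rng.choice(g, size=max(10, 2 * len(up)), replace=False)
            )
            go_truth_rows.append({"term_id": term_id, "direction": "positive"})
        elif t == 1 and down:
            members = list(down) + list(
                rng.choice(g, size=max(10, 2 * len(down)), replace=False)
            )
            go_truth_rows.append({"term_id": term_id, "direction": "negative"})
        elif t == 2 and (w > 0).sum() >= 20:
            members = list(rng.choice(g, size=20, replace=False, p=w))
            go_truth_rows.append(
                {"term_id": term_id, "direction": "length_confound_null"}
            )
        else:
            size = int(rng.integers(20, 101))
            members = list(rng.choice(g, size=min(size, g), replace=False))
        for m in sorted(set(members)):
            term_rows.append({"term_id": term_id, "gene_id": genes[m]})

    go_memberships = pd.DataFrame(term_rows, columns=["term_id", "gene_id"])
    de_truth = pd.DataFrame(de_rows, columns=["gene_id", "trait", "beta"])
    go_truth = pd.DataFrame(go_truth_rows, columns=["term_id", "direction"])
    expression_out = pd.DataFrame(
        np.exp(logx), index=expression.index, columns=expression.columns
    )
    return phenotypes, expression_out, gene_lengths, go_memberships, de_truth, go_truth
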