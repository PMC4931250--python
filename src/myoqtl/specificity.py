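"""Entropy-based tissue expression specificity index.

Given a gene x tissue expression panel (FPKM-like, non-negative) and a target
tissue (e.g. skeletal muscle), each gene g is scored by:

* relative expression ``p_{g,t} = x_{g,t} / sum_t x_{g,t}``
* Shannon entropy across tissues ``H_g = -sum_t p_{g,t} log2 p_{g,t}`` (bits)
* target-tissue specificity ``Q_g = H_g - log2(p_{g,target})`` (bits); Q = 0
  iff all expression is in the target tissue, and lower Q means more
  target-specific expression
* expression specificity index ``ESI_g = 1 - Q_g / max_g(Q_g)`` in [0, 1],
  where the maximum runs over genes with finite Q. Genes with zero target
  expression have infinite Q and are mapped to ESI = 0.

Genes are then binned into equal-count deciles of the index; decile 10 holds
the genes most highly and specifically expressed in the target tissue.
Because every step is rank- or ratio-based, scoring FPKM or TPM matrices
gives closely similar results; no pseudocount is added to zeros (genes with
an all-zero row are flagged unscorable instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TissueExpressionPanel",
    "relative_expression",
    "entropy",
    "specificity_q",
    "esi",
    "assign_deciles",
    "score_panel",
]


@dataclass
class TissueExpressionPanel:
    """Gene x tissue non-negative expression with one tissue flagged as target.

    ``x`` is a DataFrame indexed by gene id with one column per tissue.
    """

    x: pd.DataFrame
    target_tissue: str

    def __post_init__(self) -> None:
        if self.target_tissue not in self.x.columns:
            raise ValueError(f"target tissue {self.target_tissue!r} not in panel")
        if (self.x.to_numpy() < 0).any():
            raise ValueError("expression panel contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.x.index

    @property
    def tissue_ids(self) -> pd.Index:
        return self.x.columns

    @property
    def scorable(self) -> pd.Series:
        """Genes with a positive row total; all-zero rows cannot be scored."""
        return self.x.sum(axis=1) > 0


def relative_expression(panel: TissueExpressionPanel) -> pd.DataFrame:
    """Per-gene tissue proportions; rows of unscorable genes are NaN."""
    totals = panel.x.sum(axis=1)
    p = panel.x.div(totals, axis=0)
    p[totals == 0] = np.nan
    return p


def entropy(p_row: np.ndarray, atol: float = 1e-8) -> float:
    """Shannon entropy in bits of a proportion vector; 0*log2(0) == 0."""
    p = np.asarray(p_row, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative proportions")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def specificity_q(h: float, p_target: float) -> float:
    """Target-tissue specificity Q = H - log2(p_target), in bits.

    Returns ``inf`` when the gene has no target-tissue expression.
    """
    if p_target < 0:
        raise ValueError("p_target must be >= 0")
    if p_target == 0:
        return np.inf
    return h - np.log2(p_target)


def esi(q_values: np.ndarray) -> np.ndarray:
    """Specificity index 1 - Q/max(Q) over finite Q; infinite Q maps to 0."""
    q = np.asarray(q_values, dtype=float)
    finite = np.isfinite(q)
    if not finite.any():
        raise ValueError("no gene with finite Q; cannot normalize")
    qmax = q[finite].max()
    out = np.zeros_like(q)
    if qmax > 0:
        out[finite] = 1.0 - q[finite] / qmax
    else:  # all finite Q equal 0 (degenerate single-tissue panel)
        out[finite] = 1.0
    return out


def assign_deciles(scores: pd.Series) -> pd.Series:
    """Equal-count decile (1..10) per gene; decile 10 = highest score.

    Bin sizes differ by at most one. Ties are broken by a stable sort on the
    gene id so assignment is deterministic.
    """
    s = scores.dropna()
    if len(s) < 10:
        raise ValueError(f"need >= 10 scorable genes, got {len(s)}")
    frame = pd.DataFrame({"score": s})
    frame = frame.sort_index(kind="stable").sort_values("score", kind="stable")
    n = len(frame)
    # rank r (0-based) -> decile floor(r*10/n)+1 gives equal-count bins
    deciles = np.floor(np.arange(n) * 10 / n).astype(int) + 1
    out = pd.Series(deciles, index=frame.index, name="decile")
    return out.reindex(scores.index)


def score_panel(panel: TissueExpressionPanel) -> pd.DataFrame:
    """Full scoring: p_target, H, Q, specificity index and decile per gene.

    Returns a DataFrame indexed by gene with columns
    ``p_target, H_bits, Q_bits, esi, decile, scorable``. Unscorable genes
    (all-zero expression) carry NaN scores and a null decile.
    """
    p = relative_expression(panel)
    scorable = panel.scorable
    h = np.full(len(p), np.nan)
    rows = p.to_numpy()
    mask = scorable.to_numpy()
    for i in np.where(mask)[0]:
        h[i] = entropy(rows[i])
    p_target = p[panel.target_tissue].to_numpy()
    q = np.full(len(p), np.nan)
    q[mask] = [specificity_q(h[i], p_target[i]) for i in np.where(mask)[0]]
    index_vals = np.full(len(p), np.nan)
    if mask.any():
        index_vals[mask] = esi(q[mask])
    result = pd.DataFrame(
        {
            "p_target": p_target,
            "H_bits": h,
            "Q_bits": q,
            "esi": index_vals,
            "scorable": mask,
        },
        index=panel.gene_ids,
    )
    result["decile"] = assign_deciles(pd.Series(index_vals, index=panel.gene_ids))
    return result
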