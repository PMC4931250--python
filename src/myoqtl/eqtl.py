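"""cis-eQTL mapping, LD pruning, and conditional analysis of GWAS variants.

Expression is prepared by inverse-normal transform, removal of known
covariates plus top-K principal components of the covariate-residual matrix
(a latent-factor adjustment absorbing broad unmodelled structure), and a
final inverse-normal transform. Each gene is tested against every variant
within 1 Mb (inclusive) of its most upstream TSS with the additive model
``Y_ij = alpha + beta_js G_is + eps`` where G is the allele dosage; q-values
are computed across all tested pairs and associations with q <= 0.05 are
called significant.

Per-gene LD pruning keeps the lowest-p variant and drops everything with
r^2 >= 0.2 to a kept variant, greedily. The conditional analysis of a GWAS
variant holds its dosage in the model while forward-selecting other cis
variants (smallest addition p, while p < stop_p, default 0.0019); the GWAS
variant's Wald p in the final model is the conditional p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GeneAnnotation, GenotypeMatrix
from .stats import inverse_normal, qvalues, residualize

__all__ = [
    "latent_factor_adjust",
    "cis_pairs",
    "map_cis_eqtl",
    "ld_r2",
    "ld_prune_per_gene",
    "best_per_gene",
    "conditional_gwas_eqtl",
    "conditional_analysis",
    "ConditionalResult",
]

CIS_WINDOW_BP = 1_000_000
STOP_P = 0.0019


def latent_factor_adjust(
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None,
    k: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Remove known covariates and K data-driven factors from expression.

    Pipeline: per-gene inverse normal; residualize on covariates; take the
    top-K principal components (sample space) of the residual matrix and
    residualize on covariates + components; inverse normal of the residuals.
    K=0 reduces to plain covariate residualization (plus the transforms).
    """
    n = expression.shape[1]
    if k >= n:
        raise ValueError(f"K={k} must be smaller than n_samples={n}")
    if rng is None:
        rng = np.random.default_rng(0)
    X = expression.to_numpy(dtype=float)
    Y1 = np.vstack([inverse_normal(row, rng=rng) for row in X])
    resid = residualize(Y1.T, covariates).T if covariates is not None else Y1
    if k > 0:
        centered = resid - resid.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        pcs = vt[:k].T  # (n, k)
        design = (
            pd.concat(
                [
                    covariates.reset_index(drop=True),
                    pd.DataFrame(pcs, columns=[f"factor_{i+1}" for i in range(k)]),
                ],
                axis=1,
            )
            if covariates is not None
            else pd.DataFrame(pcs)
        )
        resid = residualize(Y1.T, design).T
    out = np.vstack([inverse_normal(row, rng=rng) for row in resid])
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def cis_pairs(
    genes: GeneAnnotation,
    genotypes: GenotypeMatrix,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """All (gene, variant) pairs with |pos - anchor| <= window on one chromosome.

    The window is inclusive at both boundaries and anchored at the gene's
    most upstream TSS (strand-aware).
    """
    anchors = genes.window_anchor
    var = genotypes.variants
    out = []
    by_chrom = {c: grp for c, grp in var.groupby("chrom", sort=False)}
    for row, anchor in zip(genes.genes.itertuples(), anchors):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, anchor - window_bp, side="left")
        hi = np.searchsorted(pos, anchor + window_bp, side="right")
        sel = grp.iloc[lo:hi]
        if len(sel):
            out.append(
                pd.DataFrame(
                    {
                        "gene_id": row.gene_id,
                        "variant_id": sel["id"].to_numpy(),
                        "distance": sel["pos"].to_numpy() - anchor,
                    }
                )
            )
    if not out:
        return pd.DataFrame(columns=["gene_id", "variant_id", "distance"])
    return pd.concat(out, ignore_index=True)


def map_cis_eqtl(
    Y: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    mac_min: int = 5,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-pair simple regression of expression on dosage, q across all pairs.

    Pairs whose variant has minor allele count <= ``mac_min`` or zero dosage
    variance are skipped. Returns records sorted by (gene_id, p).
    """
    dos = genotypes.dosages
    mac = np.minimum(dos.sum(axis=1), 2 * dos.shape[1] - dos.sum(axis=1))
    n = dos.shape[1]
    vidx_all = genotypes.index_of(pairs["variant_id"].to_numpy())
    results = []
    Ymat = Y.to_numpy(dtype=float)
    gene_index = pd.Index(Y.index)
    for gene_id, grp in pairs.groupby("gene_id", sort=False):
        gi = gene_index.get_loc(gene_id)
        y = Ymat[gi]
        vidx = vidx_all[grp.index.to_numpy()]
        ok = (mac[vidx] > mac_min) & (dos[vidx].std(axis=1) > 0)
        vidx = vidx[ok]
        if vidx.size == 0:
            continue
        G = dos[vidx]
        gc = G - G.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sxx = (gc**2).sum(axis=1)
        beta = (gc @ yc) / sxx
        resid_ss = (yc**2).sum() - beta**2 * sxx
        dof = n - 2
        sigma2 = np.maximum(resid_ss, 0) / dof
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2 * sps.t.sf(np.abs(t), dof)
        results.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "variant_id": genotypes.variants["id"].to_numpy()[vidx],
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "n": n,
                }
            )
        )
    if not results:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "beta", "se", "p", "n", "q"]
        )
    rec = pd.concat(results, ignore_index=True)
    rec["q"] = qvalues(rec["p"].to_numpy(), fdr_method)
    return rec.sort_values(["gene_id", "p"], kind="stable").reset_index(drop=True)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; NaN if degenerate."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.std() == 0 or g2.std() == 0:
        return np.nan
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def ld_prune_per_gene(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Greedy per-gene LD pruning: keep lowest p, drop r^2 >= threshold proxies."""
    kept_rows = []
    for gene_id, grp in records.groupby("gene_id", sort=False):
        grp = grp.sort_values("p", kind="stable")
        vids = grp["variant_id"].to_numpy()
        vidx = genotypes.index_of(vids)
        dos = genotypes.dosages[vidx]
        alive = np.ones(len(grp), dtype=bool)
        for i in range(len(grp)):
            if not alive[i]:
                continue
            kept_rows.append(grp.index[i])
            for j in range(i + 1, len(grp)):
                if alive[j]:
                    r2 = ld_r2(dos[i], dos[j])
                    if np.isfinite(r2) and r2 >= threshold:
                        alive[j] = False
    return records.loc[kept_rows].reset_index(drop=True)


def best_per_gene(records: pd.DataFrame, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """One record per gene: minimum p; exact ties broken by genomic position."""
    pos = pd.Series(
        genotypes.variants["pos"].to_numpy(),
        index=genotypes.variants["id"],
    )
    rec = records.copy()
    rec["_pos"] = pos.reindex(rec["variant_id"]).to_numpy()
    rec = rec.sort_values(["gene_id", "p", "_pos"], kind="stable")
    out = rec.drop_duplicates("gene_id", keep="first").drop(columns="_pos")
    return out.reset_index(drop=True)


@dataclass
class ConditionalResult:
    gwas_variant_id: str
    gene_id: str
    marginal_p: float
    conditional_p: float
    selected_covariate_variants: list[str]
    stopped_reason: str
    non_identifiable: bool = False


def _ols_pvalues(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Wald p per coefficient of y ~ X (X includes intercept)."""
    n, k = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - k
    sigma2 = (resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return 2 * sps.t.sf(np.abs(t), dof)


def conditional_gwas_eqtl(
    gwas_variant_id: str,
    gene_id: str,
    Y: pd.DataFrame,
    genotypes: GenotypeMatrix,
    cis_variant_ids: np.ndarray,
    stop_p: float = STOP_P,
    max_steps: int = 20,
) -> ConditionalResult:
    """Iterative conditional analysis of one GWAS-variant / gene pair.

    The GWAS variant's dosage stays in the model throughout; at each step the
    remaining cis variant with the smallest addition p-value joins the model
    while that p < ``stop_p`` (ties broken by genomic position). The reported
    conditional p is the GWAS variant's Wald p in the final model. A selected
    variant with r^2 > 0.99 to the GWAS variant marks the result
    non-identifiable.
    """
    y = Y.loc[gene_id].to_numpy(dtype=float)
    gidx = int(genotypes.index_of([gwas_variant_id])[0])
    g_gwas = genotypes.dosages[gidx]
    n = y.size

    cand_ids = [v for v in cis_variant_ids if v != gwas_variant_id]
    cand_idx = genotypes.index_of(np.array(cand_ids)) if cand_ids else np.array([], int)
    cand_pos = genotypes.variants["pos"].to_numpy()[cand_idx] if cand_ids else None

    X = np.column_stack([np.ones(n), g_gwas])
    marginal_p = float(_ols_pvalues(y, X)[1])

    selected: list[str] = []
    alive = np.ones(len(cand_ids), dtype=bool)
    non_ident = False
    while len(selected) < max_steps:
        best = None
        for j in np.where(alive)[0]:
            gj = genotypes.dosages[cand_idx[j]]
            if gj.std() == 0:
                alive[j] = False
                continue
            Xj = np.column_stack([X, gj])
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                alive[j] = False
                continue
            pj = _ols_pvalues(y, Xj)[-1]
            key = (pj, cand_pos[j])
            if best is None or key < best[0]:
                best = (key, j, Xj)
        if best is None:
            stopped_reason = "no addable candidate"
            break
        (pj, _), j, Xj = best
        if pj >= stop_p:
            stopped_reason = "no candidate below stop_p"
            break
        X = Xj
        selected.append(cand_ids[j])
        alive[j] = False
        r2 = ld_r2(g_gwas, genotypes.dosages[cand_idx[j]])
        if np.isfinite(r2) and r2 > 0.99:
            non_ident = True
    else:
        stopped_reason = "max steps reached"
    conditional_p = float(_ols_pvalues(y, X)[1])
    return ConditionalResult(
        gwas_variant_id=gwas_variant_id,
        gene_id=gene_id,
        marginal_p=marginal_p,
        conditional_p=conditional_p,
        selected_covariate_variants=selected,
        stopped_reason=stopped_reason,
        non_identifiable=non_ident,
    )


def conditional_analysis(
    gwas_pairs: pd.DataFrame,
    Y: pd.DataFrame,
    genotypes: GenotypeMatrix,
    genes: GeneAnnotation,
    stop_p: float = STOP_P,
    window_bp: int = CIS_WINDOW_BP,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Run the conditional analysis for every tested GWAS-variant / gene pair.

    ``gwas_pairs``: DataFrame with columns gwas_variant_id, gene_id.
    Marginal and conditional q-values are computed across all tested pairs.
    """
    pairs = cis_pairs(genes, genotypes, window_bp)
    by_gene = {g: grp["variant_id"].to_numpy() for g, grp in pairs.groupby("gene_id")}
    rows = []
    for rec in gwas_pairs.itertuples():
        cis_ids = by_gene.get(rec.gene_id, np.array([]))
        if rec.gwas_variant_id not in set(cis_ids):
            raise ValueError(
                f"{rec.gwas_variant_id} is not a cis variant of {rec.gene_id}"
            )
        res = conditional_gwas_eqtl(
            rec.gwas_variant_id, rec.gene_id, Y, genotypes, cis_ids, stop_p
        )
        rows.append(
            {
                "gwas_variant_id": res.gwas_variant_id,
                "gene_id": res.gene_id,
                "marginal_p": res.marginal_p,
                "conditional_p": res.conditional_p,
                "n_selected": len(res.selected_covariate_variants),
                "selected_covariate_variants": ",".join(
                    res.selected_covariate_variants
                ),
                "stopped_reason": res.stopped_reason,
                "non_identifiable": res.non_identifiable,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["marginal_q"] = qvalues(out["marginal_p"].to_numpy(), fdr_method)
        out["conditional_q"] = qvalues(out["conditional_p"].to_numpy(), fdr_method)
    return out
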