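"""Trait-gene expression association and signed-log-p GO enrichment.

Binary trait model (per gene j): ``Y_ij = alpha_j + beta_j T_i + gamma_j' Z_i
+ eps``, where Y is the rank-based inverse-normal transformed expression, T
is disease status and Z the known covariates (age, sex, batch). Quantitative
traits use a simple regression of doubly-transformed expression on the
doubly-transformed trait, both prepared by the same recipe: inverse normal ->
residualize on covariates -> inverse normal of the residuals.

GO enrichment regresses term membership on the signed -log10 association
p-value with a logistic model that includes log10 gene length, guarding
against the length-power confound: ``logit(pi_j) = alpha + beta P_j +
gamma L_j``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import inverse_normal, qvalues, residualize

__all__ = [
    "transform_trait",
    "transform_expression",
    "t2d_association",
    "quant_trait_association",
    "signed_logp",
    "go_enrichment",
    "present_go_terms",
    "cluster_go_betas",
]


def _ols_many(Y: np.ndarray, X: np.ndarray, test_col: int):
    """OLS of each row of Y (genes x samples) on shared design X.

    Returns (beta, se, p, resid_var, all_coefs) for the tested column.
    """
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # (k, n)
    coefs = Y @ H.T  # (g, k)
    resid = Y - coefs @ X.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * XtX_inv[test_col, test_col])
    beta = coefs[:, test_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * sps.t.sf(np.abs(tstat), dof)
    return beta, se, p, sigma2, coefs


def transform_trait(values, covariates, rng=None) -> np.ndarray:
    """Quantitative-trait recipe: inverse normal -> residualize -> inverse normal."""
    step1 = inverse_normal(np.asarray(values, dtype=float), rng=rng)
    resid = residualize(step1, covariates)
    return inverse_normal(resid, rng=rng)


def transform_expression(
    expression: pd.DataFrame, covariates=None, rng=None, double: bool = True
) -> pd.DataFrame:
    """Per-gene inverse-normal transform, optionally residualized and re-transformed.

    With ``double=False`` only the first inverse-normal step is applied
    (the preparation used by the binary-trait model, which keeps covariates
    inside the regression instead).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty(expression.shape)
    X = expression.to_numpy(dtype=float)
    for i in range(X.shape[0]):
        y = inverse_normal(X[i], rng=rng)
        if double and covariates is not None:
            y = inverse_normal(residualize(y, covariates), rng=rng)
        out[i] = y
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def t2d_association(
    Y: pd.DataFrame,
    status: np.ndarray,
    covariates: pd.DataFrame,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-gene OLS of inverse-normal expression on binary disease status.

    ``Y``: genes x samples inverse-normal transformed expression. Covariates
    are included in the model. Returns a DataFrame indexed by gene with
    beta, se, p, q, intercept and residual variance.
    """
    t = np.asarray(status, dtype=float)
    if set(np.unique(t)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if t.sum() == 0 or t.sum() == t.size:
        raise ValueError("one disease-status class is empty")
    from .stats import _design_matrix

    if covariates is None:
        Z = np.ones((t.size, 1))
    else:
        Z, _ = _design_matrix(covariates)
    X = np.column_stack([Z, t])
    beta, se, p, sigma2, coefs = _ols_many(Y.to_numpy(dtype=float), X, X.shape[1] - 1)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p": p,
            "q": qvalues(p, fdr_method),
            "intercept": coefs[:, 0],
            "residual_variance": sigma2,
        },
        index=Y.index,
    )


def quant_trait_association(
    Y: pd.DataFrame, x: np.ndarray, fdr_method: str = "bh", min_n: int = 10
) -> pd.DataFrame:
    """Simple regression of doubly-transformed expression on a transformed trait."""
    x = np.asarray(x, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.size}")
    X = np.column_stack([np.ones(x.size), x])
    beta, se, p, sigma2, coefs = _ols_many(Y.to_numpy(dtype=float), X, 1)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p": p,
            "q": qvalues(p, fdr_method),
            "intercept": coefs[:, 0],
            "residual_variance": sigma2,
        },
        index=Y.index,
    )


def signed_logp(assoc: pd.DataFrame) -> pd.Series:
    """Signed -log10 p: positive when higher expression goes with higher trait."""
    p = np.clip(assoc["p"].to_numpy(), 1e-300, 1.0)
    return pd.Series(
        -np.log10(p) * np.sign(assoc["beta"].to_numpy()), index=assoc.index
    )


def go_enrichment(
    signed_logp_per_gene: pd.Series,
    log10_gene_length: pd.Series,
    memberships: pd.DataFrame,
    min_genes: int = 10,
    include_length: bool = True,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-term logistic regression of membership on signed -log10 p (+ length).

    ``memberships``: DataFrame with columns term_id, gene_id. Terms covering
    fewer than ``min_genes`` scored genes, no genes, or all genes are skipped
    (recorded with a skip reason and NaN statistics).
    """
    import statsmodels.api as sm

    genes = signed_logp_per_gene.index
    P = signed_logp_per_gene.to_numpy(dtype=float)
    L = log10_gene_length.reindex(genes).to_numpy(dtype=float)
    cols = [P, L] if include_length else [P]
    X = sm.add_constant(np.column_stack(cols))
    rows = []
    for term_id, grp in memberships.groupby("term_id", sort=True):
        member = genes.isin(set(grp["gene_id"])).astype(float)
        n_genes = int(member.sum())
        skip = None
        if n_genes < min_genes:
            skip = f"fewer than {min_genes} scored genes"
        elif n_genes == len(genes):
            skip = "term contains all genes"
        if skip is None:
            try:
                fit = sm.GLM(member, X, family=sm.families.Binomial()).fit()
                beta, pval = fit.params[1], fit.pvalues[1]
                gamma = fit.params[2] if include_length else np.nan
                intercept = fit.params[0]
            except Exception as exc:  # perfect separation etc.
                skip, beta, pval, gamma, intercept = (
                    f"fit failed: {exc}",
                    np.nan,
                    np.nan,
                    np.nan,
                    np.nan,
                )
        if skip is not None:
            beta = pval = gamma = intercept = np.nan
        rows.append(
            {
                "term_id": term_id,
                "beta_enrich": beta,
                "gamma_length": gamma,
                "intercept": intercept,
                "p": pval,
                "n_genes": n_genes,
                "skip_reason": skip,
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    ok = out["p"].notna()
    out["q"] = np.nan
    out.loc[ok, "q"] = qvalues(out.loc[ok, "p"].to_numpy(), fdr_method)
    out["direction"] = np.sign(out["beta_enrich"])
    return out


def present_go_terms(
    results_per_trait: dict[str, pd.DataFrame],
    memberships: pd.DataFrame,
    k: int = 20,
    jaccard_threshold: float = 0.5,
) -> pd.DataFrame:
    """Top-k ranked GO terms per trait and direction, redundancy-pruned.

    Per trait and sign of enrichment the k most significant terms are ranked
    1..k; a term appearing in several lists keeps its lowest rank; then terms
    whose gene-set Jaccard overlap with a better-ranked kept term exceeds the
    threshold are pruned.
    """
    entries = []
    for trait, res in results_per_trait.items():
        ok = res[res["p"].notna()]
        for direction, sign in (("positive", 1), ("negative", -1)):
            sub = ok[np.sign(ok["beta_enrich"]) == sign].sort_values(
                "p", kind="stable"
            )
            top = sub.head(k)
            for rank, (term_id, row) in enumerate(top.iterrows(), start=1):
                entries.append(
                    {
                        "term_id": term_id,
                        "trait": trait,
                        "direction": direction,
                        "rank": rank,
                        "p": row["p"],
                        "beta_enrich": row["beta_enrich"],
                    }
                )
    if not entries:
        return pd.DataFrame(
            columns=["term_id", "trait", "direction", "rank", "p", "beta_enrich"]
        )
    table = pd.DataFrame(entries)
    # lowest rank per term across traits/directions
    best = table.sort_values(["rank", "p"], kind="stable").drop_duplicates("term_id")
    gene_sets = {
        t: set(g["gene_id"]) for t, g in memberships.groupby("term_id", sort=False)
    }
    kept: list[str] = []
    pruned = []
    for row in best.itertuples():
        gs = gene_sets.get(row.term_id, set())
        redundant = False
        for prev in kept:
            ps = gene_sets.get(prev, set())
            union = gs | ps
            if union and len(gs & ps) / len(union) > jaccard_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(row.term_id)
            pruned.append(row)
    return pd.DataFrame(pruned).drop(columns="Index").reset_index(drop=True)


def cluster_go_betas(beta_matrix: pd.DataFrame) -> np.ndarray:
    """Complete-linkage hierarchical clustering order of GO-term beta vectors.

    Presentation-only helper: returns the leaf order from complete linkage on
    Euclidean distances between per-trait enrichment coefficients.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    link = hierarchy.linkage(
        pdist(beta_matrix.to_numpy(), metric="euclidean"), method="complete"
    )
    return np.asarray(hierarchy.leaves_list(link))
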