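"""Shared statistical primitives: rank transforms, residualization, FDR.

These are the building blocks of every downstream analysis: the rank-based
inverse-normal transform applied to expression and quantitative traits,
covariate residualization, Benjamini-Hochberg FDR and Storey q-values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

__all__ = [
    "inverse_normal",
    "residualize",
    "bh_fdr",
    "storey_qvalues",
    "qvalues",
]


def inverse_normal(
    values: np.ndarray,
    rng: np.random.Generator | None = None,
    offset: float = 0.5,
) -> np.ndarray:
    """Rank-based inverse-normal transform with random tie breaking.

    Maps value of rank ``r`` (1-based) among ``n`` to ``Phi^-1((r - offset)/n)``.
    Tied observations are ordered uniformly at random under ``rng`` so that the
    output has no atoms; the transform is strictly monotone over untied values.

    Parameters
    ----------
    values : 1-D array of finite numbers, length >= 2.
    rng : seeded generator used only to permute ties; defaults to a fixed seed
        so repeated calls are reproducible.
    offset : rank offset ``c`` in ``(r - c)/n``; 0.5 by default.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("inverse_normal expects a 1-D array")
    if x.size < 2:
        raise ValueError("need at least 2 values to rank-transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in inverse_normal input")
    if rng is None:
        rng = np.random.default_rng(0)
    n = x.size
    # random permutation first, then stable sort: uniform order among ties
    perm = rng.permutation(n)
    order = perm[np.argsort(x[perm], kind="stable")]
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return sps.norm.ppf((ranks - offset) / n)


def _design_matrix(covariates) -> tuple[np.ndarray, list[str]]:
    """Build a full design matrix (intercept + columns) from an array or DataFrame.

    Categorical / object columns of a DataFrame are dummy-coded dropping the
    first level. Returns the matrix and its column names.
    """
    import pandas as pd

    if covariates is None:
        return np.ones((0, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        cols = [np.ones(len(covariates))]
        names = ["intercept"]
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=str(c), drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    names.append(str(dc))
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(str(c))
        return np.column_stack(cols), names
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    names = ["intercept"] + [f"z{i}" for i in range(z.shape[1])]
    return np.column_stack([np.ones(z.shape[0]), z]), names


def residualize(values: np.ndarray, covariates) -> np.ndarray:
    """Residuals of ``values`` after OLS on covariates (intercept always included).

    ``values`` may be 1-D (n,) or 2-D (n, m) to residualize many columns against
    the same design. Raises a ``ValueError`` naming collinear columns when the
    design is rank deficient.
    """
    y = np.asarray(values, dtype=float)
    one_d = y.ndim == 1
    if one_d:
        y = y[:, None]
    X, names = _design_matrix(covariates)
    if X.shape[0] == 0:
        X = np.ones((y.shape[0], 1))
    if X.shape[0] != y.shape[0]:
        raise ValueError("values and covariates have different lengths")
    # constant covariate columns are absorbed by the intercept, not an error
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    X = X[:, keep]
    names = [names[j] for j in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.ones((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid[:, 0] if one_d else resid


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), monotone in p."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def storey_qvalues(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    min_m_for_spline: int = 100,
) -> np.ndarray:
    """Storey q-values with smoothed pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 and smoothed with a cubic
    spline evaluated at the largest lambda. For small collections
    (m < ``min_m_for_spline``) the pi0 estimate is unstable, so the
    conservative pi0 = 1 (Benjamini-Hochberg) is used instead.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < min_m_for_spline:
        pi0 = 1.0
    else:
        pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        try:
            spline = UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spline(lambdas[-1]))
        except Exception:
            pi0 = float(pi0_l[-1])
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def qvalues(pvalues: np.ndarray, method: str = "bh") -> np.ndarray:
    """Dispatch to ``bh_fdr`` or ``storey_qvalues`` by name."""
    if method == "bh":
        return bh_fdr(pvalues)
    if method == "storey":
        return storey_qvalues(pvalues)
    raise ValueError(f"unknown FDR method: {method!r}")
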