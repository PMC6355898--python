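"""Latent factor structure of the speech measures.

A principal components analysis of the standardized block-level measure
table, retaining components with eigenvalues greater than one and
applying an oblique promax rotation (kappa = 4) to aid interpretation.
Factor scores are computed by the regression method and can be used as
predictors of neural activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorModel",
    "FactorScores",
    "extract_factors",
    "factor_scores",
    "varimax",
    "promax",
    "tucker_congruence",
    "match_factors",
]


@dataclass
class FactorModel:
    loadings: pd.DataFrame  # measures x factors (promax pattern matrix)
    unrotated_loadings: pd.DataFrame
    n_factors: int
    rotation: str
    explained_variance_fraction: float  # from unrotated components
    factor_correlations: np.ndarray  # oblique factor intercorrelations
    eigenvalues: np.ndarray
    correlation: np.ndarray  # fit-sample measure correlation matrix
    column_means: pd.Series  # standardization constants of the fit sample
    column_sds: pd.Series


@dataclass
class FactorScores:
    scores: pd.DataFrame  # block x factors


def varimax(loadings: np.ndarray, gamma: float = 1.0, max_iter: int = 500,
            tol: float = 1e-10) -> np.ndarray:
    """Kaiser-normalized varimax rotation; returns the rotation matrix."""
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    h = np.sqrt((loadings ** 2).sum(axis=1))
    A = loadings / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        G = A.T @ (L ** 3 - (gamma / p) * L * (L ** 2).sum(axis=0))
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return R


def promax(loadings: np.ndarray, kappa: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation of a loading matrix.

    Varimax first; the varimax solution raised (elementwise, sign
    preserved) to the power kappa serves as the target, and the oblique
    transformation is the least-squares map onto that target with
    columns scaled to unit-variance factors. Returns the pattern matrix
    and the factor intercorrelation matrix.
    """
    k = loadings.shape[1]
    if k < 2:
        return loadings.copy(), np.eye(k)
    Rv = varimax(loadings)
    X = loadings @ Rv
    target = np.abs(X) ** kappa * np.sign(X)
    U = np.linalg.solve(X.T @ X, X.T @ target)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    pattern = X @ U
    phi = np.linalg.inv(U.T @ U)
    return pattern, phi


def extract_factors(block_table: pd.DataFrame, kappa: int = 4) -> FactorModel:
    """PCA with eigenvalue-greater-than-one retention and promax rotation.

    Rows with any missing measure are dropped; columns are z-scored
    using the fit sample's mean and SD (stored for scoring). Explained
    variance is reported on the unrotated retained components.
    """
    X = block_table.dropna(axis=0)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} complete rows, got {n}")
    means = X.mean()
    sds = X.std(ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"constant (collinear) columns: {zero_var}")
    Z = (X - means) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    if np.linalg.matrix_rank(R) < p:
        gram = pd.DataFrame(R, index=X.columns, columns=X.columns)
        dep = [c for c in X.columns
               if (gram[c].abs().drop(c) > 1 - 1e-10).any()]
        raise ValueError(f"rank-deficient measure table; collinear columns: {dep}")
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_keep = max(1, int(np.sum(eigval > 1.0)))
    L = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    # fix component signs for reproducibility
    for j in range(n_keep):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    pattern, phi = promax(L, kappa=kappa)
    names = [f"factor{j + 1}" for j in range(n_keep)]
    return FactorModel(
        loadings=pd.DataFrame(pattern, index=X.columns, columns=names),
        unrotated_loadings=pd.DataFrame(L, index=X.columns, columns=names),
        n_factors=n_keep,
        rotation=f"promax(kappa={kappa})" if n_keep > 1 else "none",
        explained_variance_fraction=float(eigval[:n_keep].sum() / p),
        factor_correlations=phi,
        eigenvalues=eigval,
        correlation=R,
        column_means=means,
        column_sds=sds,
    )


def factor_scores(model: FactorModel, block_table: pd.DataFrame) -> FactorScores:
    """Regression-method factor scores.

    Scores = Z R^{-1} S where S is the structure matrix (pattern times
    factor correlations). Over the fitted rows each factor's scores are
    mean-zero. Requires the same columns as at fit time.
    """
    cols = list(model.column_means.index)
    if list(block_table.columns) != cols:
        raise ValueError(
            f"column mismatch: expected {cols}, got {list(block_table.columns)}"
        )
    X = block_table.dropna(axis=0)
    Z = ((X - model.column_means) / model.column_sds).to_numpy()
    structure = model.loadings.to_numpy() @ model.factor_correlations
    W = np.linalg.solve(model.correlation, structure)
    scores = Z @ W
    return FactorScores(
        scores=pd.DataFrame(scores, index=X.index, columns=model.loadings.columns)
    )


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def match_factors(est: np.ndarray, planted: np.ndarray) -> tuple[np.ndarray, float]:
    """Match estimated to planted factors by maximum |congruence|.

    Sign and order of factors are arbitrary, so matching maximizes the
    total absolute congruence over permutations (Hungarian assignment).
    Returns the per-pair |congruence| values and their mean.
    """
    k_e, k_p = est.shape[1], planted.shape[1]
    C = np.zeros((k_e, k_p))
    for i in range(k_e):
        for j in range(k_p):
            C[i, j] = abs(tucker_congruence(est[:, i], planted[:, j]))
    rows, cols = linear_sum_assignment(-C)
    vals = C[rows, cols]
    return vals, float(vals.mean())
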