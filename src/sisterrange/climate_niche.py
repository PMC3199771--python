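"""Climatic-niche distances: varimax-rotated PCA plus Mahalanobis distances.

Per-locality climate variables (mixed units) are z-scored, reduced by PCA with
the Kaiser criterion (eigenvalue > 1 before rotation), and the retained
loadings varimax-rotated to simple structure.  Species are then compared by
squared Mahalanobis distance between their mean score vectors, scaled by the
pooled within-species covariance of the scores — the natural choice when each
species contributes several localities.  The resulting distance matrix serves
as the bioclimatic covariate of spatial distance in the factorial regressions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = ["PCAResult", "pca_varimax", "mahalanobis_matrix"]

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame       # rows = localities; columns PC1..PCk (rotated)
    loadings: pd.DataFrame     # variables × retained PCs, varimax-rotated
    eigenvalues: np.ndarray    # unrotated eigenvalues of retained PCs
    rotated_ssq: np.ndarray    # per-rotated-factor sums of squared loadings
    species: pd.Series         # species label per score row


def pca_varimax(
    climate: pd.DataFrame, eigen_min: float = 1.0, max_iter: int = 500, tol: float = 1e-8
) -> PCAResult:
    """PCA of the climate table with Kaiser retention and varimax rotation.

    Variables are standardized to z-scores, so the eigenvalues are those of
    the correlation matrix; components with eigenvalue > ``eigen_min`` are
    kept, their loadings (eigenvector × sqrt(eigenvalue)) rotated with the
    normalized-Kaiser varimax criterion, and rotated scores returned by the
    regression method.
    """
    value_cols = [c for c in climate.columns if c != "species"]
    X = climate[value_cols].to_numpy(float)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 climate variables")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [value_cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant climate columns: {bad}")
    if n <= m:
        warnings.warn("fewer localities than variables; PCA will be unstable")
    Z = (X - X.mean(axis=0)) / sd

    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eigen_min
    k = int(keep.sum())
    if k < 1:
        raise ValueError(f"no component with eigenvalue > {eigen_min}")
    if np.any(np.abs(eigval - eigen_min) < 0.05):
        warnings.warn("eigenvalues near the retention threshold; retained "
                      "component count is unstable")
    lam = eigval[:k]
    loadings = eigvec[:, :k] * np.sqrt(lam)

    if k == 1:
        rotated = loadings
    else:
        # Kaiser normalization: rotate rows scaled to unit communality, then
        # restore the scale.
        comm = np.sqrt((loadings ** 2).sum(axis=1))
        comm[comm == 0] = 1.0
        rot_norm, _ = rotate_factors(
            loadings / comm[:, None], "varimax", max_tries=max_iter, tol=tol
        )
        rotated = rot_norm * comm[:, None]
    # Canonical order/sign: factors by decreasing explained variance, each with
    # a positive loading sum.
    ssq = (rotated ** 2).sum(axis=0)
    order = np.argsort(ssq)[::-1]
    rotated = rotated[:, order]
    signs = np.where(rotated.sum(axis=0) < 0, -1.0, 1.0)
    rotated = rotated * signs
    ssq = (rotated ** 2).sum(axis=0)

    # Regression-method scores on the rotated axes.
    scores = Z @ rotated @ np.linalg.inv(rotated.T @ rotated)
    pc_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, columns=pc_names, index=climate.index),
        loadings=pd.DataFrame(rotated, index=value_cols, columns=pc_names),
        eigenvalues=lam,
        rotated_ssq=ssq,
        species=climate["species"].reset_index(drop=True),
    )


def mahalanobis_matrix(
    scores: pd.DataFrame,
    species_labels: pd.Series,
    covariance: str = "pooled",
) -> pd.DataFrame:
    """Squared Mahalanobis distances between species mean score vectors.

    ``D²(s, t) = (m_s - m_t)' S⁻¹ (m_s - m_t)`` with S the pooled
    within-species covariance of the scores (``covariance="identity"`` gives
    plain squared Euclidean distances on the standardized scores).
    Single-locality species contribute no degrees of freedom to S; if the
    pooled matrix is singular the pseudo-inverse is used (logged).
    """
    S_scores = np.asarray(scores, float)
    labels = np.asarray(species_labels)
    species = sorted(set(labels))
    k = S_scores.shape[1]

    means = {}
    pooled = np.zeros((k, k))
    dof = 0
    for sp in species:
        rows = S_scores[labels == sp]
        means[sp] = rows.mean(axis=0)
        if rows.shape[0] > 1:
            dev = rows - means[sp]
            pooled += dev.T @ dev
            dof += rows.shape[0] - 1

    if covariance == "identity" or dof < k:
        if covariance != "identity":
            log.warning(
                "pooled covariance rank-deficient (dof=%d < k=%d); "
                "falling back to identity scaling", dof, k,
            )
        S_inv = np.eye(k)
    else:
        S = pooled / dof
        try:
            S_inv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            log.warning("singular pooled covariance; using pseudo-inverse")
            S_inv = np.linalg.pinv(S)

    n = len(species)
    D2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = means[species[i]] - means[species[j]]
            D2[i, j] = D2[j, i] = float(d @ S_inv @ d)
    return pd.DataFrame(D2, index=species, columns=species)
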