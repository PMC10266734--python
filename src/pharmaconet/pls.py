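"""Partial least squares correlation between two regional data matrices.

With X the regions x receptors density matrix and Y the regions x drugs
contrast matrix, both column z-scored, the method is a single SVD of the
cross-product::

    X' Y = U S V'

U rows index receptors, V rows index drugs; the i-th columns of U and V
form a latent variable whose singular value s_i measures the covariance it
captures, with effect size s_i^2 / sum_j s_j^2. Regional scores are the
projections of the z-scored data onto the singular vectors, and loadings
are the Pearson correlations of each original variable with the score
pattern. This is symmetric (correlation-flavored) PLS: one decomposition,
no deflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import RegionalMatrix, check_region_match

__all__ = [
    "PLSResult",
    "zscore_array",
    "zscore_columns",
    "pls_svd",
    "covariance_explained",
    "loadings",
    "loading_ci",
]


def zscore_array(M: np.ndarray) -> np.ndarray:
    """Column z-score with sample (n-1) standard deviation."""
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance column at index {bad}")
    return (M - M.mean(axis=0)) / sd


def zscore_columns(M: RegionalMatrix) -> RegionalMatrix:
    """Column-wise z-scoring of a regional table (names the offending column)."""
    sd = M.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = M.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance column: {bad!r}")
    return RegionalMatrix(M.region_ids, M.columns, zscore_array(M.values))


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve per-component sign indeterminacy deterministically.

    The entry of U with the largest absolute value in each column is forced
    positive (ties broken by the first index), and V is flipped with U.
    """
    flips = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flips[flips == 0] = 1.0
    return U * flips, V * flips


@dataclass
class PLSResult:
    """Full output of one PLS correlation decomposition."""

    receptor_names: list[str]
    drug_names: list[str]
    region_ids: list[str]
    receptor_weights: np.ndarray   # U: receptors x components, orthonormal columns
    drug_weights: np.ndarray       # V: drugs x components, orthonormal columns
    singular_values: np.ndarray    # descending, >= 0
    cov_explained: np.ndarray      # per-component fraction, sums to 1
    receptor_scores: np.ndarray    # regions x components: zscore(X) @ U
    drug_scores: np.ndarray        # regions x components: zscore(Y) @ V
    receptor_loadings: np.ndarray  # receptors x components
    drug_loadings: np.ndarray      # drugs x components

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def pls_svd(X: RegionalMatrix, Y: RegionalMatrix) -> PLSResult:
    """PLS correlation of receptor densities X and drug-contrast maps Y.

    Both matrices are column z-scored internally; the number of components
    is min(#receptors, #drugs). Loadings for receptor and drug variables
    alike are correlations with the receptor (neurotransmitter) score
    pattern of the corresponding component.
    """
    check_region_match(X.region_ids, Y.region_ids, "X and Y")
    Xz = zscore_array(X.values)
    Yz = zscore_array(Y.values)
    R = Xz.T @ Yz  # receptors x drugs cross-product
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    rx = Xz @ U
    ry = Yz @ V
    return PLSResult(
        receptor_names=list(X.columns),
        drug_names=list(Y.columns),
        region_ids=list(X.region_ids),
        receptor_weights=U,
        drug_weights=V,
        singular_values=s,
        cov_explained=covariance_explained(s),
        receptor_scores=rx,
        drug_scores=ry,
        receptor_loadings=loadings(X.values, rx),
        drug_loadings=loadings(Y.values, rx),
    )


def covariance_explained(singular_values: np.ndarray) -> np.ndarray:
    """Effect size per component: s_i^2 / sum_j s_j^2."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    total = np.sum(s**2)
    if total == 0:
        raise ValueError("all singular values are zero")
    return s**2 / total


def loadings(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each data column with each score column."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if data.shape[0] != scores.shape[0]:
        raise ValueError("data and scores must share the region dimension")
    dz = zscore_array(data)
    sz = zscore_array(scores)
    n = data.shape[0]
    return dz.T @ sz / (n - 1)


def loading_ci(data: np.ndarray, scores: np.ndarray, n_boot: int = 1000,
               seed: int = 0, level: float = 0.95) -> np.ndarray:
    """Percentile bootstrap CI for loadings, resampling regions with replacement.

    Returns an array of shape (n_variables, n_score_columns, 2) holding the
    lower and upper percentile bounds.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = data.shape[0]
    if n < 10:
        raise ValueError("too few regions for a bootstrap (need >= 10)")
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, data.shape[1], scores.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        d, s = data[idx], scores[idx]
        # resampling can flatten a column; retry once with a fresh draw
        while np.any(d.std(axis=0) == 0) or np.any(s.std(axis=0) == 0):
            idx = rng.integers(0, n, size=n)
            d, s = data[idx], scores[idx]
        boots[b] = loadings(d, s)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return np.stack([lo, hi], axis=-1)
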