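"""Network fusion and diffusion-map embedding of similarity networks.

Similarity networks over the same parcellation are fused by horizontal
concatenation of their rows followed by a row-wise normalized-angle
affinity (1 - arccos(cosine)/pi, mapping row angles into [0, 1]). The
fused affinity is embedded with a diffusion map: degree-corrected
anisotropic normalization with parameter alpha (alpha = 0.5 retains the
global relations between points), row-normalization into a Markov
transition operator, eigendecomposition, and per-component scaling by
lambda / (1 - lambda) (the diffusion-time t = 0 convention). The resulting
components, ordered by decreasing eigenvalue, are the "gradients".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .datatypes import SimilarityMatrix, check_region_match

__all__ = [
    "GradientResult",
    "normalized_angle_affinity",
    "fuse_networks",
    "diffusion_embedding",
    "variance_fraction",
]


@dataclass
class GradientResult:
    region_ids: list[str]
    embedding: np.ndarray        # regions x components, arbitrary units
    eigenvalues: np.ndarray      # decreasing, trivial component removed
    variance_fraction: np.ndarray


def normalized_angle_affinity(M: np.ndarray, region_ids: list[str],
                              sparsity: float = 0.0) -> SimilarityMatrix:
    """Row-wise normalized angle similarity of a regions x features array.

    Cosine similarity between rows is clamped into [-1, 1] and mapped by
    ``1 - arccos(c) / pi`` into [0, 1]: identical rows -> 1, orthogonal
    rows -> 0.5, antiparallel rows -> 0. With ``sparsity`` in (0, 1), only
    the strongest ``(1 - sparsity)`` fraction of entries per row is kept
    before symmetrization by transpose-averaging.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        bad = region_ids[int(np.flatnonzero(norms == 0)[0])]
        raise ValueError(f"zero-norm row: {bad!r}")
    unit = M / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)  # self-angle is exactly zero
    if sparsity > 0:
        if not sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        n = aff.shape[0]
        keep = max(1, int(np.ceil((1.0 - sparsity) * n)))
        thresh = np.sort(aff, axis=1)[:, n - keep][:, None]
        aff = np.where(aff >= thresh, aff, 0.0)
        aff = (aff + aff.T) / 2.0
        np.fill_diagonal(aff, 1.0)
    return SimilarityMatrix(region_ids, aff)


def fuse_networks(sims: list[SimilarityMatrix],
                  sparsity: float = 0.0) -> SimilarityMatrix:
    """Fuse similarity networks by row concatenation + normalized-angle affinity."""
    if not sims:
        raise ValueError("need at least one similarity matrix")
    first = sims[0]
    for s in sims[1:]:
        check_region_match(first.region_ids, s.region_ids, "fused networks")
    concat = np.hstack([s.values for s in sims])
    return normalized_angle_affinity(concat, list(first.region_ids), sparsity=sparsity)


def diffusion_embedding(affinity: SimilarityMatrix, alpha: float = 0.5,
                        n_components: int = 10,
                        allow_disconnected: bool = False) -> GradientResult:
    """Diffusion-map embedding of a non-negative symmetric affinity matrix.

    The anisotropic kernel ``W~ = D^-alpha W D^-alpha`` (D the degree
    diagonal) is row-normalized into a transition matrix whose spectrum is
    obtained through the symmetric conjugate operator; the constant leading
    eigenvector is discarded and each remaining eigenvector is scaled by
    ``lambda / (1 - lambda)``. Components carry a deterministic sign
    (largest-magnitude entry positive).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    W = affinity.values
    if np.any(W < 0):
        raise ValueError("affinity must be non-negative")
    n_comp_graph, labels = connected_components(W > 0, directed=False)
    if n_comp_graph > 1:
        if not allow_disconnected:
            raise ValueError(
                f"affinity graph has {n_comp_graph} components; pass "
                "allow_disconnected=True to embed anyway")
        warnings.warn("affinity graph is disconnected; embedding the full graph")
    d = W.sum(axis=1)
    if np.any(d == 0):
        raise ValueError("isolated node with zero degree")
    Wt = W / np.outer(d**alpha, d**alpha)
    dt = Wt.sum(axis=1)
    # symmetric conjugate of the row-normalized transition matrix
    A = Wt / np.sqrt(np.outer(dt, dt))
    A = (A + A.T) / 2.0
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # Anchor the leading eigenspace to the analytic stationary vector
    # sqrt(dt): under degeneracy (disconnected graphs) eigh may return
    # component indicators instead, which would leak into the gradients.
    v0 = np.sqrt(dt)
    v0 /= np.linalg.norm(v0)
    m = int(np.sum(evals > evals[0] - 1e-10))
    basis = [v0]
    for j in range(m):
        w = evecs[:, j].copy()
        for b in basis:
            w -= (b @ w) * b
        nrm = np.linalg.norm(w)
        if nrm > 1e-8:
            basis.append(w / nrm)
    evecs[:, :m] = np.column_stack(basis[:m])
    # eigenvectors of the transition matrix itself
    psi = evecs / np.sqrt(dt)[:, None]
    # drop the trivial stationary component (eigenvalue 1, constant psi)
    lam = evals[1:1 + n_components]
    psi = psi[:, 1:1 + n_components]
    lam_clip = np.clip(lam, None, 1.0 - 1e-12)
    emb = psi * (lam_clip / (1.0 - lam_clip))[None, :]
    # deterministic sign: largest-|value| entry positive per component
    flips = np.sign(emb[np.argmax(np.abs(emb), axis=0), np.arange(emb.shape[1])])
    flips[flips == 0] = 1.0
    emb = emb * flips
    return GradientResult(
        region_ids=list(affinity.region_ids),
        embedding=emb,
        eigenvalues=lam,
        variance_fraction=variance_fraction(lam),
    )


def variance_fraction(eigenvalues: np.ndarray) -> np.ndarray:
    """Share of each retained component: lambda_i / sum over retained lambdas."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise ValueError("no positive eigenvalue mass to apportion")
    return lam / total
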