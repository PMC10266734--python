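"""Spatially informed inference for parcellated brain maps.

Contains the spatial-autocorrelation-preserving spin test (random sphere
rotations with nearest-parcel reassignment, hemispheres handled by
mirrored rotations), the subject-level condition-permutation null for the
PLS singular values, Benjamini-Hochberg FDR control, and the
distance-dependent train/test split that cross-validates the latent-score
correlation on spatially distant held-out regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ParcellationGeometry,
    RegionalMatrix,
    SubjectScanPair,
    check_region_match,
)
from .fc import subject_delta
from .io import euclidean_distance_matrix
from .pls import pls_svd, zscore_array

__all__ = [
    "SpinEnsemble",
    "build_spins",
    "spin_pvalue_pls",
    "permutation_pvalue_conditions",
    "spin_pvalue_correlation",
    "fdr_bh",
    "distance_dependent_cv",
    "CrossValResult",
]


@dataclass
class SpinEnsemble:
    """Precomputed spin reassignments: entry [k, t] is the source region
    whose value target region t inherits under rotation k."""

    assignment: np.ndarray  # (n_spins, n_regions) int
    n_spins: int
    seed: int
    region_ids: list[str]

    def apply(self, values: np.ndarray, k: int) -> np.ndarray:
        """Spin a per-region map (or regions x columns array) with rotation k."""
        return np.asarray(values)[self.assignment[k]]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via QR of a Gaussian matrix, det +1."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))  # make decomposition unique => Haar uniform
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _hemisphere_units(geometry: ParcellationGeometry):
    """Unit-sphere projections of the centroids, centered per hemisphere."""
    sides = []
    for side in ("L", "R"):
        idx = np.flatnonzero(geometry.hemisphere_mask(side))
        if idx.size == 0:
            continue
        pts = geometry.centroids[idx]
        pts = pts - pts.mean(axis=0)
        norms = np.linalg.norm(pts, axis=1)
        if np.any(norms < 1e-9):
            raise ValueError("degenerate centroid at hemisphere sphere center")
        sides.append((side, idx, pts / norms[:, None]))
    return sides


def spin_assignment_for_rotation(geometry: ParcellationGeometry,
                                 Q: np.ndarray) -> np.ndarray:
    """Parcel reassignment induced by one rotation Q (x-mirrored on the right).

    Every original parcel inherits the value of the closest rotated parcel
    of its own hemisphere (great-circle distance, ties broken by the lowest
    region index); the map may be non-bijective, as the nearest-parcel rule
    allows. The identity rotation yields the identity assignment.
    """
    mirror = np.diag([-1.0, 1.0, 1.0])
    assignment = np.empty(geometry.n_regions, dtype=np.intp)
    for side, idx, unit in _hemisphere_units(geometry):
        Qh = Q if side == "L" else mirror @ Q @ mirror
        rotated = unit @ Qh.T
        # nearest on the sphere = largest dot product; argmax ties -> lowest index
        sim = unit @ rotated.T
        assignment[idx] = idx[np.argmax(sim, axis=1)]
    return assignment


def build_spins(geometry: ParcellationGeometry, n_spins: int,
                seed: int = 0) -> SpinEnsemble:
    """Build an ensemble of spin reassignments at the parcel resolution.

    Per spin, one uniform random rotation is applied to the left-hemisphere
    centroids projected onto the unit sphere (centered per hemisphere), and
    its x-mirrored version to the right hemisphere; parcels then inherit
    values by the nearest-rotated-parcel rule of
    :func:`spin_assignment_for_rotation`. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    assignment = np.empty((n_spins, geometry.n_regions), dtype=np.intp)
    for k in range(n_spins):
        assignment[k] = spin_assignment_for_rotation(geometry, _random_rotation(rng))
    return SpinEnsemble(assignment=assignment, n_spins=n_spins, seed=seed,
                        region_ids=list(geometry.region_ids))


def _null_proportion(null: np.ndarray, obs, conservative: bool) -> np.ndarray:
    null = np.atleast_2d(null)
    exceed = (null > obs).sum(axis=0).astype(float)
    if conservative:
        return (exceed + 1.0) / (null.shape[0] + 1.0)
    return exceed / null.shape[0]


def spin_pvalue_pls(X: RegionalMatrix, Y: RegionalMatrix, spins: SpinEnsemble,
                    conservative: bool = False) -> np.ndarray:
    """Spin-test p-values for the PLS singular values, one per component.

    Each null sample reruns the PLS decomposition on the original X and a
    spun Y; p_i is the proportion of null singular values at rank i that
    exceed the observed one in magnitude.
    """
    check_region_match(X.region_ids, spins.region_ids, "X and spin ensemble")
    check_region_match(Y.region_ids, spins.region_ids, "Y and spin ensemble")
    obs = pls_svd(X, Y).singular_values
    null = np.empty((spins.n_spins, obs.size))
    for k in range(spins.n_spins):
        Yk = RegionalMatrix(Y.region_ids, Y.columns, spins.apply(Y.values, k))
        null[k] = pls_svd(X, Yk).singular_values
    return _null_proportion(null, obs, conservative)


def permutation_pvalue_conditions(X: RegionalMatrix,
                                  scans: dict[str, list[SubjectScanPair]],
                                  n_perm: int = 1000, seed: int = 0,
                                  conservative: bool = False) -> np.ndarray:
    """Condition-permutation p-values for the PLS singular values.

    The null permutes, independently per subject (fair coin), the drug and
    baseline condition labels before recomputing subject delta maps and
    dataset means. Because a subject's delta map is exactly antisymmetric
    under the swap, the permuted deltas are sign flips of the observed
    ones; subject deltas are therefore computed once and sign-flipped.
    """
    deltas = {d: np.column_stack([subject_delta(p) for p in pairs])
              for d, pairs in scans.items()}
    names = list(deltas)
    if all(np.max(np.abs(deltas[d])) == 0 for d in names):
        raise ValueError("degenerate null: every subject delta map is identically zero")
    Y_obs = np.column_stack([deltas[d].mean(axis=1) for d in names])
    Ymat = RegionalMatrix(X.region_ids, names, Y_obs)
    obs = pls_svd(X, Ymat).singular_values
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    for k in range(n_perm):
        cols = []
        for d in names:
            D = deltas[d]
            signs = rng.choice([-1.0, 1.0], size=D.shape[1])
            cols.append((D * signs).mean(axis=1))
        Yk = np.column_stack(cols)
        if np.any(Yk.std(axis=0, ddof=1) == 0):
            raise ValueError("degenerate null: permuted contrast map is constant")
        null[k] = pls_svd(X, RegionalMatrix(X.region_ids, names, Yk)).singular_values
    return _null_proportion(null, obs, conservative)


def spin_pvalue_correlation(mapA: np.ndarray, mapB: np.ndarray,
                            spins: SpinEnsemble, method: str = "rank",
                            conservative: bool = False) -> tuple[float, float]:
    """Spatial Spearman correlation of two regional maps with a spin null.

    The null spins mapB; the p-value is two-sided, the proportion of null
    |rho| at least as large as the observed |rho|.
    """
    a = np.asarray(mapA, dtype=float).ravel()
    b = np.asarray(mapB, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map has no defined rank correlation")
    if method != "rank":
        raise ValueError("only rank (Spearman) correlation is supported")
    obs = stats.spearmanr(a, b).statistic
    null = np.empty(spins.n_spins)
    for k in range(spins.n_spins):
        null[k] = stats.spearmanr(a, spins.apply(b, k)).statistic
    exceed = float(np.sum(np.abs(null) >= np.abs(obs)))
    if conservative:
        p = (exceed + 1.0) / (spins.n_spins + 1.0)
    else:
        p = exceed / spins.n_spins
    return float(obs), p


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejected mask, adjusted p-values).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class CrossValResult:
    mean_r: float
    split_r: np.ndarray
    p_value: float
    null_mean_r: np.ndarray


def distance_dependent_cv(X: RegionalMatrix, Y: RegionalMatrix,
                          geometry: ParcellationGeometry,
                          train_frac: float = 0.75, n_splits: int = 100,
                          n_perm: int = 1000, seed: int = 0) -> CrossValResult:
    """Cross-validate the component-1 score correlation on distant regions.

    Per split, a random source region is drawn; the training set is the
    ``round(train_frac * n)`` regions closest to it in centroid Euclidean
    distance (ties broken by region order) and the test set the remaining,
    spatially distant, regions. PLS is fitted on the training rows; the
    held-out rows — z-scored with the training means and SDs — are
    projected onto the trained singular vectors, and the Pearson
    correlation between held-out receptor and drug scores of component 1
    is recorded. The permuted null re-evaluates the mean correlation with
    the held-out drug scores row-permuted.
    """
    check_region_match(X.region_ids, Y.region_ids, "X and Y")
    check_region_match(X.region_ids, geometry.region_ids, "X and geometry")
    if n_splits < 1:
        raise ValueError("need at least one split")
    n = geometry.n_regions
    n_train = int(round(train_frac * n))
    if n - n_train < 3:
        raise ValueError("fewer than 3 test regions; lower train_frac")
    dist = euclidean_distance_matrix(geometry).values
    rng = np.random.default_rng(seed)
    split_r = np.empty(n_splits)
    test_scores = []  # (x_scores, y_scores) per split, reused by the null
    for s in range(n_splits):
        src = int(rng.integers(0, n))
        order = np.argsort(dist[src], kind="stable")
        train, test = order[:n_train], order[n_train:]
        Xtr = X.values[train]
        Ytr = Y.values[train]
        mx, sx = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        my, sy = Ytr.mean(axis=0), Ytr.std(axis=0, ddof=1)
        if np.any(sx == 0) or np.any(sy == 0):
            raise ValueError("degenerate training split: constant column")
        R = ((Xtr - mx) / sx).T @ ((Ytr - my) / sy)
        U, _, Vt = np.linalg.svd(R, full_matrices=False)
        u1, v1 = U[:, 0], Vt[0]
        xs = ((X.values[test] - mx) / sx) @ u1
        ys = ((Y.values[test] - my) / sy) @ v1
        split_r[s] = stats.pearsonr(xs, ys).statistic
        test_scores.append((xs, ys))
    mean_r = float(split_r.mean())
    null_means = np.empty(n_perm)
    for k in range(n_perm):
        rs = np.empty(n_splits)
        for s, (xs, ys) in enumerate(test_scores):
            perm = rng.permutation(ys.size)
            rs[s] = stats.pearsonr(xs, ys[perm]).statistic
        null_means[k] = rs.mean()
    p = float(np.mean(null_means >= mean_r))
    return CrossValResult(mean_r=mean_r, split_r=split_r, p_value=p,
                          null_mean_r=null_means)
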