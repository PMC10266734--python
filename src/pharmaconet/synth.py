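"""Synthetic parcellated data with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the inputs of a pharmacological
brain-map study: spatially autocorrelated regional maps (Gaussian process
with an exponential kernel over centroid distances), a receptor-density
panel, drug-contrast maps whose cross-covariance with the receptors has a
planted low-rank latent structure, per-subject BOLD time series realizing a
planted FC weighted-degree change, and disorder abnormality maps whose
regional co-susceptibility is coupled to the pharmacological one.

All generators are pure functions of (parameters, seed). A master seed is
split into independent per-purpose child streams via ``numpy.SeedSequence``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import (
    ParcellationGeometry,
    PlantedTruth,
    RegionalMatrix,
    SubjectScanPair,
)
from .io import euclidean_distance_matrix
from .pls import zscore_array

__all__ = [
    "make_geometry",
    "sample_smooth_map",
    "make_receptor_panel",
    "plant_drug_effects",
    "make_subject_scans",
    "make_disorder_maps",
    "SPHERE_RADIUS_MM",
]

SPHERE_RADIUS_MM = 70.0
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _rng(seed, purpose: int) -> np.random.Generator:
    """Child generator for one purpose; independent streams per fixed offset."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(purpose,)))


def make_geometry(n_regions: int, seed: int = 0) -> ParcellationGeometry:
    """Parcel centroids on a 70-mm sphere, split into mirrored hemispheres.

    Half the regions are placed on the x > 0 hemisphere by a Fibonacci
    (low-discrepancy) lattice rotated by a seeded angle about the x axis;
    the other half is their x-mirror. Deterministic for a fixed seed.
    """
    if n_regions < 4 or n_regions % 2:
        raise ValueError("n_regions must be even and at least 4")
    m = n_regions // 2
    i = np.arange(m)
    # lattice on the x>0 hemisphere: x in (0, 1), spiral in the (y, z) plane
    x = (i + 0.5) / m
    r = np.sqrt(1.0 - x**2)
    phi = i * _GOLDEN_ANGLE + _rng(seed, 0).uniform(0, 2 * np.pi)
    right = np.column_stack([x, r * np.cos(phi), r * np.sin(phi)]) * SPHERE_RADIUS_MM
    left = right * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    hemisphere = ["L"] * m + ["R"] * m
    region_ids = [f"L{j:03d}" for j in range(m)] + [f"R{j:03d}" for j in range(m)]
    return ParcellationGeometry(region_ids, centroids, hemisphere)


def _exp_kernel_chol(geometry: ParcellationGeometry, lengthscale: float,
                     sigma: float, jitter: float = 1e-8) -> np.ndarray:
    d = euclidean_distance_matrix(geometry).values
    K = sigma**2 * np.exp(-d / lengthscale)
    return np.linalg.cholesky(K + jitter * sigma**2 * np.eye(len(d)))


def sample_smooth_map(geometry: ParcellationGeometry, lengthscale: float = 30.0,
                      sigma: float = 1.0, seed: int = 0,
                      name: str = "map") -> RegionalMatrix:
    """One spatially autocorrelated regional map.

    Draw from a zero-mean Gaussian process with covariance
    ``sigma^2 * exp(-d_ij / lengthscale)`` over centroid distances; small
    jitter is added to the kernel diagonal for positive definiteness.
    """
    if lengthscale <= 0 or sigma <= 0:
        raise ValueError("lengthscale and sigma must be positive")
    L = _exp_kernel_chol(geometry, lengthscale, sigma)
    z = _rng(seed, 1).standard_normal(geometry.n_regions)
    return RegionalMatrix(geometry.region_ids, [name], (L @ z)[:, None])


def make_receptor_panel(geometry: ParcellationGeometry, n_receptors: int = 19,
                        lengthscale: float = 30.0, seed: int = 0,
                        nonnegative: bool = True) -> RegionalMatrix:
    """Independent smooth maps, one per receptor/transporter column.

    Emulates a panel of PET-derived regional density maps (19 maps over a
    100-region cortical parcellation in the motivating study). Columns are
    optionally shifted to be non-negative, as densities are.
    """
    if n_receptors < 2:
        raise ValueError("need at least 2 receptors")
    L = _exp_kernel_chol(geometry, lengthscale, 1.0)
    z = _rng(seed, 2).standard_normal((geometry.n_regions, n_receptors))
    vals = L @ z
    if nonnegative:
        vals = vals - vals.min(axis=0, keepdims=True)
    cols = [f"receptor_{j:02d}" for j in range(n_receptors)]
    return RegionalMatrix(geometry.region_ids, cols, vals)


def plant_drug_effects(X: RegionalMatrix, geometry: ParcellationGeometry,
                       n_drugs: int = 15, k_latent: int = 1, snr: float = 4.0,
                       lengthscale: float = 30.0, seed: int = 0,
                       ) -> tuple[RegionalMatrix, PlantedTruth]:
    """Drug-contrast maps Y with a planted receptor->drug latent structure.

    ``Y = zscore(X) @ W @ C + E`` with W (receptors x k_latent) and
    C (k_latent x drugs) drawn once from the seed, and E independent smooth
    GP noise scaled per column so that planted-signal variance over noise
    variance equals *snr*. ``snr=np.inf`` plants a noiseless panel.
    """
    p = X.n_columns
    if not 1 <= k_latent <= min(p, n_drugs):
        raise ValueError("k_latent out of range")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = _rng(seed, 3)
    W = rng.standard_normal((p, k_latent))
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    C = rng.standard_normal((k_latent, n_drugs))
    Xz = zscore_array(X.values)
    signal = Xz @ W @ C
    if np.isinf(snr):
        Y = signal
    else:
        Lc = _exp_kernel_chol(geometry, lengthscale, 1.0)
        E = Lc @ rng.standard_normal((geometry.n_regions, n_drugs))
        sig_var = signal.var(axis=0, ddof=1)
        noise_var = E.var(axis=0, ddof=1)
        E = E * np.sqrt(sig_var / (snr * noise_var))[None, :]
        Y = signal + E
    cols = [f"drug_{j:02d}" for j in range(n_drugs)]
    Ymat = RegionalMatrix(X.region_ids, cols, Y)
    truth = PlantedTruth(true_weights=W[:, 0], true_delta=Xz @ W[:, 0],
                         noiseless_y=signal)
    return Ymat, truth


def _squash(delta: np.ndarray) -> np.ndarray:
    """Bounded squashing of a planted map into (-1, 1), scale-free."""
    sd = delta.std()
    if sd == 0:
        return np.zeros_like(delta)
    return np.tanh(delta / sd)


def _nearest_psd(A: np.ndarray, floor: float = 0.0) -> np.ndarray:
    w, V = np.linalg.eigh((A + A.T) / 2.0)
    if w.min() >= floor:
        return A
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def make_subject_scans(geometry: ParcellationGeometry, true_delta: np.ndarray,
                       n_subjects: int = 15, n_timepoints: int = 250,
                       effect_gain: float = 1.0, seed: int = 0,
                       n_factors: int = 10) -> list[SubjectScanPair]:
    """Baseline/drug BOLD pairs realizing a planted weighted-degree change.

    A baseline covariance ``S0 = B B' + diag`` comes from a random low-rank
    factor model; the drug covariance scales row/column i of S0 by
    ``sqrt(1 + effect_gain * s(true_delta_i))`` with ``s`` a tanh squashing
    keeping the scale factors inside (0.5, 1.5) for gains up to 1, and the
    diagonal restored to S0's so the perturbation acts on correlations.
    Each subject's factor loadings receive independent 5% relative jitter,
    and both conditions are sampled as stationary Gaussian series.
    """
    n = geometry.n_regions
    true_delta = np.asarray(true_delta, dtype=float)
    if true_delta.shape != (n,):
        raise ValueError("true_delta must be one value per region")
    if n_timepoints < 50:
        raise ValueError("need at least 50 time points")
    if effect_gain < 0:
        raise ValueError("effect_gain must be non-negative")
    if n_timepoints < 2 * n:
        warnings.warn("fewer than 2x regions time points; FC estimates will be noisy")
    rng = _rng(seed, 4)
    B = rng.standard_normal((n, n_factors)) / np.sqrt(n_factors)
    g = np.sqrt(np.clip(1.0 + effect_gain * _squash(true_delta), 0.25, 2.25))
    scans = []
    for s in range(n_subjects):
        Bs = B * (1.0 + 0.05 * rng.standard_normal((n, n_factors)))
        S0 = Bs @ Bs.T + np.eye(n)
        S1 = S0 * np.outer(g, g)
        np.fill_diagonal(S1, np.diag(S0))
        S1 = _nearest_psd(S1, floor=1e-10)
        L0 = np.linalg.cholesky(S0 + 1e-10 * np.eye(n))
        L1 = np.linalg.cholesky(S1 + 1e-10 * np.eye(n))
        base = L0 @ rng.standard_normal((n, n_timepoints))
        drug = L1 @ rng.standard_normal((n, n_timepoints))
        scans.append(SubjectScanPair(f"sub-{s:02d}", base, drug))
    return scans


def make_disorder_maps(true_deltas: RegionalMatrix, geometry: ParcellationGeometry,
                       n_disorders: int = 11, coupling: float = 0.5,
                       lengthscale: float = 30.0, seed: int = 0) -> RegionalMatrix:
    """Disorder abnormality maps with tunable coupling to the drug deltas.

    Each disorder map is ``coupling * (random mixture of drug delta maps)
    + (1 - coupling) * independent smooth map``, column z-scored to emulate
    standardized effect-size (Cohen's d) maps. ``coupling=1`` ties disorder
    co-susceptibility to the pharmacological one; ``coupling=0`` decouples
    them entirely.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = _rng(seed, 5)
    D = zscore_array(true_deltas.values)
    mix = rng.standard_normal((true_deltas.n_columns, n_disorders))
    shared = zscore_array(D @ mix)
    L = _exp_kernel_chol(geometry, lengthscale, 1.0)
    indep = zscore_array(L @ rng.standard_normal((geometry.n_regions, n_disorders)))
    vals = zscore_array(coupling * shared + (1.0 - coupling) * indep)
    cols = [f"disorder_{j:02d}" for j in range(n_disorders)]
    return RegionalMatrix(true_deltas.region_ids, cols, vals)
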