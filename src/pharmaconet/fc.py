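"""Functional-connectivity features: weighted degree and drug-minus-baseline deltas.

For each subject and condition, regional BOLD signals are correlated
pairwise (Pearson) into a region-by-region FC matrix; negative edges are
removed (clipped to zero) and the positive weighted degree — the sum of
each region's positive connections — is taken per region. A subject's
delta map is degree(drug) - degree(baseline); a dataset's contrast map is
the across-subject mean delta.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DeltaMapSet, SimilarityMatrix, SubjectScanPair
from .pls import zscore_array

__all__ = [
    "functional_connectivity",
    "positive_weighted_degree",
    "subject_delta",
    "aggregate_dataset",
    "regress_covariate_from_deltas",
]


def functional_connectivity(ts: np.ndarray,
                            region_ids: list[str] | None = None) -> SimilarityMatrix:
    """Pearson correlation FC matrix from a regions x time BOLD array."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a regions x time matrix with at least 3 time points")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region {bad} has zero temporal variance")
    fc = np.corrcoef(ts)
    np.fill_diagonal(fc, 1.0)
    if region_ids is None:
        region_ids = [str(i) for i in range(ts.shape[0])]
    return SimilarityMatrix(region_ids, fc)


def positive_weighted_degree(fc: SimilarityMatrix) -> np.ndarray:
    """Per-region sum of positive off-diagonal FC edges (diagonal excluded)."""
    W = fc.values.copy()
    np.fill_diagonal(W, 0.0)
    return np.clip(W, 0.0, None).sum(axis=1)


def subject_delta(pair: SubjectScanPair) -> np.ndarray:
    """Within-subject change in positive weighted degree, drug minus baseline."""
    deg_drug = positive_weighted_degree(functional_connectivity(pair.drug_ts))
    deg_base = positive_weighted_degree(functional_connectivity(pair.baseline_ts))
    return deg_drug - deg_base


def aggregate_dataset(deltas: list[np.ndarray], dataset_id: str,
                      region_ids: list[str]) -> DeltaMapSet:
    """Stack per-subject delta maps; the dataset contrast is their mean."""
    if not deltas:
        raise ValueError("need at least one subject delta")
    n = len(region_ids)
    arrs = []
    for d in deltas:
        d = np.asarray(d, dtype=float)
        if d.shape != (n,):
            raise ValueError("subject delta region count mismatch")
        arrs.append(d)
    return DeltaMapSet(dataset_id, region_ids, np.column_stack(arrs))


def regress_covariate_from_deltas(Y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residualize each region's row of dataset contrasts on a scalar covariate.

    The covariate (one scalar per dataset column, e.g. the difference in
    mean framewise displacement between conditions) is standardized, and
    each region's values are replaced by the residuals of an ordinary
    least-squares fit with intercept — so residual rows have zero mean and
    are exactly orthogonal to the covariate.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (Y.shape[1],):
        raise ValueError("covariate length must equal number of dataset columns")
    if covariate.std(ddof=1) == 0:
        raise ValueError("covariate has zero variance")
    c = zscore_array(covariate[:, None])[:, 0]
    D = np.column_stack([np.ones_like(c), c])  # datasets x 2 design
    beta, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    return Y - (D @ beta).T
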