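"""Core labeled containers for parcellated brain-map analysis.

Every container carries its region labels so downstream stages can
re-validate alignment; silent reordering of parcellated data is the
classic source of spurious brain-map correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationGeometry",
    "RegionalMatrix",
    "SimilarityMatrix",
    "SubjectScanPair",
    "PlantedTruth",
    "DeltaMapSet",
    "check_region_match",
]

_SYM_TOL = 1e-10


def _as_str_list(labels: Sequence) -> list[str]:
    return [str(x) for x in labels]


def check_region_match(a: Sequence[str], b: Sequence[str], what: str = "inputs") -> None:
    """Raise ValueError unless the two region-label sequences are identical in order."""
    if list(a) != list(b):
        raise ValueError(f"region labels of {what} do not match (order-sensitive)")


@dataclass(frozen=True)
class ParcellationGeometry:
    """Region identities, 3-D centroid coordinates (mm) and hemisphere labels.

    Anchors the spin rotations and all Euclidean-distance computations.
    """

    region_ids: list[str]
    centroids: np.ndarray  # (n, 3) mm
    hemisphere: list[str]  # 'L' or 'R' per region
    network: list[str] | None = None

    def __post_init__(self):
        object.__setattr__(self, "region_ids", _as_str_list(self.region_ids))
        cent = np.asarray(self.centroids, dtype=float)
        object.__setattr__(self, "centroids", cent)
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise ValueError("region_ids must be unique")
        if cent.shape != (n, 3):
            raise ValueError(f"centroids must be ({n}, 3), got {cent.shape}")
        if not np.all(np.isfinite(cent)):
            raise ValueError("centroids must be finite")
        hemi = list(self.hemisphere)
        if len(hemi) != n or not set(hemi) <= {"L", "R"}:
            raise ValueError("hemisphere must be a per-region list of 'L'/'R'")
        object.__setattr__(self, "hemisphere", hemi)
        if self.network is not None and len(self.network) != n:
            raise ValueError("network labels must match region count")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemisphere_mask(self, side: str) -> np.ndarray:
        return np.array([h == side for h in self.hemisphere])


@dataclass
class RegionalMatrix:
    """Labeled regions x variables table of real values.

    Holds receptor densities X, drug-contrast maps Y, disorder maps and
    hierarchy maps alike; single-column instances serve as regional maps.
    """

    region_ids: list[str]
    columns: list[str]
    values: np.ndarray  # (n_regions, n_columns)

    def __post_init__(self):
        self.region_ids = _as_str_list(self.region_ids)
        self.columns = _as_str_list(self.columns)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        self.values = vals
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate column names")
        if vals.shape != (len(self.region_ids), len(self.columns)):
            raise ValueError(
                f"values shape {vals.shape} inconsistent with "
                f"{len(self.region_ids)} regions x {len(self.columns)} columns"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite (no missing entries)")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.region_ids, name="region"),
                            columns=self.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionalMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def reorder(self, region_ids: Sequence[str]) -> "RegionalMatrix":
        """Reorder rows to the given labels; raise if any label is absent."""
        idx = {r: i for i, r in enumerate(self.region_ids)}
        missing = [r for r in region_ids if str(r) not in idx]
        if missing:
            raise ValueError(f"regions missing from table: {missing[:5]}")
        order = [idx[str(r)] for r in region_ids]
        return RegionalMatrix(_as_str_list(region_ids), list(self.columns),
                              self.values[order])


@dataclass
class SimilarityMatrix:
    """Symmetric region x region matrix (FC, co-susceptibility, affinity...)."""

    region_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.region_ids = _as_str_list(self.region_ids)
        vals = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if vals.shape != (n, n):
            raise ValueError(f"expected ({n}, {n}) matrix, got {vals.shape}")
        offdiag = vals[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(offdiag)):
            raise ValueError("off-diagonal entries must be finite")
        asym = np.nanmax(np.abs(vals - vals.T)) if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix asymmetric beyond tolerance (max |A-A'| = {asym:.3g})")
        # enforce exact symmetry
        self.values = (vals + vals.T) / 2.0

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def upper_values(self) -> np.ndarray:
        """Strictly-upper-triangular entries, row-major (i < j)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass
class SubjectScanPair:
    """One subject's region x time BOLD matrices under baseline and drug."""

    subject_id: str
    baseline_ts: np.ndarray
    drug_ts: np.ndarray
    motion_fd: tuple[float, float] | None = None  # mean FD (mm) per condition

    def __post_init__(self):
        self.baseline_ts = np.asarray(self.baseline_ts, dtype=float)
        self.drug_ts = np.asarray(self.drug_ts, dtype=float)
        if self.baseline_ts.shape[0] != self.drug_ts.shape[0]:
            raise ValueError("baseline and drug scans must share region count/order")

    @property
    def n_regions(self) -> int:
        return self.baseline_ts.shape[0]

    def swapped(self) -> "SubjectScanPair":
        fd = None if self.motion_fd is None else (self.motion_fd[1], self.motion_fd[0])
        return SubjectScanPair(self.subject_id, self.drug_ts, self.baseline_ts, fd)


@dataclass
class PlantedTruth:
    """Ground truth planted by the synthetic generators, for recovery tests."""

    true_weights: np.ndarray          # per-receptor planted weight vector (k=1 latent)
    true_delta: np.ndarray            # per-region planted FC-degree change pattern
    coupling: float = 0.0             # disorder-drug co-susceptibility coupling in [0,1]
    noiseless_y: np.ndarray | None = None  # regions x drugs planted signal


@dataclass
class DeltaMapSet:
    """Per-dataset subject-wise and mean drug-minus-baseline degree-change maps."""

    dataset_id: str
    region_ids: list[str]
    subject_deltas: np.ndarray  # (n_regions, n_subjects)
    mean_delta: np.ndarray = field(init=False)

    def __post_init__(self):
        self.region_ids = _as_str_list(self.region_ids)
        self.subject_deltas = np.atleast_2d(np.asarray(self.subject_deltas, dtype=float))
        if self.subject_deltas.shape[0] != len(self.region_ids):
            raise ValueError("subject_deltas rows must match region count")
        self.mean_delta = self.subject_deltas.mean(axis=1)

    @property
    def n_subjects(self) -> int:
        return self.subject_deltas.shape[1]
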