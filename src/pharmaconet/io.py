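"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated with '.' decimals:

* regional tables — header row of variable names, first column ``region``;
* similarity matrices — first row and first column are region labels;
* geometry — columns ``region, x, y, z, hemisphere[, network]``.

Region order is always taken from the geometry; readers reorder tables to
a supplied geometry and fail loudly on any mismatch.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ParcellationGeometry, RegionalMatrix, SimilarityMatrix

__all__ = [
    "read_regional_table",
    "write_regional_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_geometry",
    "write_geometry",
    "upper_triangle_edges",
    "euclidean_distance_matrix",
]

_FLOAT_FMT = "%.17g"  # shortest exact representation round-trips doubles


def read_regional_table(path, geometry: ParcellationGeometry | None = None) -> RegionalMatrix:
    """Read a regions x variables TSV into a validated :class:`RegionalMatrix`.

    If *geometry* is given, rows are reordered to match its region order and a
    ``ValueError`` is raised when any geometry region is absent from the table.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in {path}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate region labels in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    mat = RegionalMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if geometry is not None:
        mat = mat.reorder(geometry.region_ids)
    return mat


def write_regional_table(mat: RegionalMatrix, path) -> None:
    df = mat.to_frame()
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_similarity_matrix(path, geometry: ParcellationGeometry | None = None) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"similarity matrix in {path} must have identical row/column labels")
    sim = SimilarityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
    if geometry is not None and sim.region_ids != geometry.region_ids:
        raise ValueError("similarity matrix regions do not match geometry")
    return sim


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.region_ids, columns=sim.region_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="region")


def read_geometry(path) -> ParcellationGeometry:
    df = pd.read_csv(path, sep="\t")
    required = {"region", "x", "y", "z", "hemisphere"}
    if not required <= set(df.columns):
        raise ValueError(f"geometry file {path} must have columns {sorted(required)}")
    network = list(df["network"].astype(str)) if "network" in df.columns else None
    return ParcellationGeometry(
        region_ids=list(df["region"].astype(str)),
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=list(df["hemisphere"].astype(str)),
        network=network,
    )


def write_geometry(geom: ParcellationGeometry, path) -> None:
    df = pd.DataFrame({
        "region": geom.region_ids,
        "x": geom.centroids[:, 0],
        "y": geom.centroids[:, 1],
        "z": geom.centroids[:, 2],
        "hemisphere": geom.hemisphere,
    })
    if geom.network is not None:
        df["network"] = geom.network
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def upper_triangle_edges(n: int) -> tuple[np.ndarray, int]:
    """Strictly-upper-triangular (i < j) index pairs and their count n(n-1)/2.

    These are the unique region pairs over which edgewise matrix
    correlations are computed (4950 for a 100-region parcellation,
    2278 for 68 regions).
    """
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)
    return pairs, pairs.shape[0]


def euclidean_distance_matrix(geometry: ParcellationGeometry) -> SimilarityMatrix:
    """Pairwise Euclidean distances (mm) between parcel centroids."""
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(geometry.centroids))
    return SimilarityMatrix(geometry.region_ids, d)
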