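"""Fixed-radius spatial neighborhoods and neighbor-mean features.

For each cell, neighbors are all other cells of the *same biopsy* within a
Euclidean radius (closed ball, boundary inclusive). The spatial feature for
a protein is the arithmetic mean of that protein over the neighbors; a cell
with no neighbors gets an all-zero feature row. One radius is used per
model; radius 0 encodes the non-spatial baseline.

Neighbor discovery uses a kd-tree per biopsy but is contractually equal to
the all-pairs distance computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import SingleCellTable
from .panel import ProteinPanel

#: radii (µm) evaluated in the benchmark; 0 = no spatial features
DEFAULT_RADII = (0.0, 15.0, 30.0, 60.0, 90.0, 120.0)


@dataclass(frozen=True)
class NeighborIndex:
    """Per-cell neighbor row positions (into the source table's row order)."""

    radius: float
    neighbors: tuple[np.ndarray, ...]  # row positions, one array per cell
    cell_keys: tuple[tuple[str, str], ...]  # (biopsy_id, cell_id) per row

    @property
    def n_cells(self) -> int:
        return len(self.neighbors)

    def counts(self) -> np.ndarray:
        return np.array([len(a) for a in self.neighbors])


def find_neighbors(table: SingleCellTable, radius: float) -> NeighborIndex:
    """Exact fixed-radius neighbor sets, computed per biopsy.

    Distance ≤ radius, self excluded; neighbor relations never cross biopsy
    boundaries (tissue sections are physically distinct).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    n = table.n_cells
    neighbors: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n)]
    biopsies = table.data["biopsy_id"].to_numpy()
    xy = table.data[["x", "y"]].to_numpy(float)
    for bid in np.unique(biopsies):
        rows = np.flatnonzero(biopsies == bid)
        if rows.size == 1:
            continue
        tree = cKDTree(xy[rows])
        pairs = tree.query_pairs(radius, output_type="ndarray")
        adj: list[list[int]] = [[] for _ in range(rows.size)]
        for i, j in pairs:
            adj[i].append(j)
            adj[j].append(i)
        for local, nbrs in enumerate(adj):
            neighbors[rows[local]] = rows[np.sort(np.asarray(nbrs, dtype=np.int64))]
    keys = tuple(
        zip(table.data["biopsy_id"].astype(str), table.data["cell_id"].astype(str))
    )
    return NeighborIndex(radius=radius, neighbors=tuple(neighbors), cell_keys=keys)


def neighborhood_means(
    table: SingleCellTable,
    index: NeighborIndex,
    panel: ProteinPanel | None = None,
) -> pd.DataFrame:
    """Mean protein abundance over each cell's neighbors.

    Returns a DataFrame with one ``<protein>_nbr<radius>`` column per panel
    protein plus ``neighbor_count``; rows align with ``table``. Cells with
    no neighbors get exactly 0 for every protein.
    """
    panel = panel or table.panel
    if not table.scaled:
        raise ValueError("neighbor features are defined on scaled intensities")
    keys = tuple(
        zip(table.data["biopsy_id"].astype(str), table.data["cell_id"].astype(str))
    )
    if keys != index.cell_keys:
        raise ValueError("neighbor index was not built on this table")
    vals = table.data[panel.names].to_numpy(float)
    out = np.zeros((table.n_cells, len(panel)))
    counts = np.zeros(table.n_cells, dtype=int)
    for i, nbrs in enumerate(index.neighbors):
        if nbrs.size:
            out[i] = vals[nbrs].mean(axis=0)
            counts[i] = nbrs.size
    suffix = _radius_suffix(index.radius)
    df = pd.DataFrame(out, columns=[f"{p}_nbr{suffix}" for p in panel.names])
    df["neighbor_count"] = counts
    return df


def _radius_suffix(radius: float) -> str:
    return str(int(radius)) if float(radius).is_integer() else str(radius)


def augment(
    table: SingleCellTable,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concatenate own intensities with neighbor-mean features.

    With ``features=None`` (the radius-0 baseline) the result is the plain
    P-column intensity matrix; otherwise P own + P neighbor-mean columns, in
    stable order (panel order, then neighbor columns in panel order).
    """
    own = table.data[table.panel.names].reset_index(drop=True)
    if features is None:
        return own.copy()
    if len(features) != len(own):
        raise ValueError(
            f"feature rows ({len(features)}) != table rows ({len(own)})"
        )
    nbr_cols = [c for c in features.columns if c != "neighbor_count"]
    return pd.concat(
        [own, features[nbr_cols].reset_index(drop=True)], axis=1
    )


def spatial_features(
    table: SingleCellTable, radius: float
) -> pd.DataFrame:
    """Build the model input matrix for one radius (0 = non-spatial)."""
    if radius == 0:
        return augment(table, None)
    index = find_neighbors(table, radius)
    return augment(table, neighborhood_means(table, index))


def neighbor_column(protein: str, radius: float) -> str:
    return f"{protein}_nbr{_radius_suffix(radius)}"
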