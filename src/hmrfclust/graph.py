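"""Spatial neighborhood graph over 3-D voxel coordinates.

Voxels live on an integer grid (grid units; physical voxel size is
irrelevant to the model).  The neighborhood system is 6-connectivity: two
voxels are neighbors iff their coordinates differ by exactly 1 along one
axis and 0 along the others.  Surface voxels and voxels next to holes simply
have fewer neighbors; there is no padding or wraparound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["VoxelGraph", "build_graph", "permute_coordinates", "full_grid_coords"]

# unit offsets along each axis, both directions
_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class VoxelGraph:
    """Undirected 6-neighborhood graph over voxels.

    Attributes
    ----------
    coords : ndarray of shape (N, 3), int
        Voxel coordinates; row i is the position of voxel i.
    edges : ndarray of shape (E, 2), int
        Unordered voxel-index pairs stored once with ``edges[:, 0] < edges[:, 1]``,
        sorted lexicographically.
    """

    coords: np.ndarray
    edges: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix (both directions of every edge);
        built once and cached."""
        cached = getattr(self, "_adjacency", None)
        if cached is not None:
            return cached
        n = self.n_voxels
        if self.n_edges == 0:
            adj = sp.csr_matrix((n, n))
        else:
            i, j = self.edges[:, 0], self.edges[:, 1]
            data = np.ones(2 * self.n_edges)
            adj = sp.csr_matrix(
                (data, (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n)
            )
        object.__setattr__(self, "_adjacency", adj)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_voxels, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        """Neighbor indices per voxel (both directions)."""
        adj = self.adjacency()
        return [adj.indices[adj.indptr[i] : adj.indptr[i + 1]] for i in range(self.n_voxels)]


def build_graph(coords: np.ndarray) -> VoxelGraph:
    """Build the 6-neighborhood graph from integer voxel coordinates.

    Parameters
    ----------
    coords : array-like of shape (N, 3)
        Unique integer coordinate rows; row order defines the voxel index and
        must align with the rows of the expression matrix.

    Raises
    ------
    ValueError
        If coordinates are not integer N x 3, or contain duplicate rows
        (duplicates are named in the message).
    """
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coordinates must be N x 3, got shape {coords.shape}")
    if not np.issubdtype(coords.dtype, np.integer):
        rounded = np.round(coords)
        if not np.array_equal(coords, rounded):
            raise ValueError("coordinates must be integers (grid units)")
        coords = rounded
    coords = coords.astype(np.int64)

    index = {}
    for i, row in enumerate(map(tuple, coords)):
        if row in index:
            raise ValueError(
                f"duplicate coordinate rows: rows {index[row]} and {i} are both {row}"
            )
        index[row] = i

    edges = []
    for i, row in enumerate(coords):
        for off in _OFFSETS[::2]:  # positive directions only: each pair found once
            j = index.get(tuple(row + off))
            if j is not None:
                edges.append((i, j) if i < j else (j, i))
    if edges:
        edge_arr = np.array(sorted(edges), dtype=np.int64)
    else:
        edge_arr = np.empty((0, 2), dtype=np.int64)
    return VoxelGraph(coords=coords, edges=edge_arr)


def permute_coordinates(graph: VoxelGraph, seed: int | np.random.Generator) -> VoxelGraph:
    """Randomly reassign the coordinate rows to voxel indices.

    This destroys the spatial component of the data (expression rows are
    shuffled relative to positions) while preserving the coordinate multiset
    and hence the degree sequence of the graph.  Used as the spatial
    randomization control.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(graph.n_voxels)
    return build_graph(graph.coords[perm])


def full_grid_coords(shape: tuple[int, int, int]) -> np.ndarray:
    """Coordinates of every voxel of a full ``L x M x P`` grid, 0-based."""
    L, M, P = shape
    if L < 1 or M < 1 or P < 1:
        raise ValueError(f"grid dimensions must be positive, got {shape}")
    grid = np.indices((L, M, P)).reshape(3, -1).T
    return np.ascontiguousarray(grid.astype(np.int64))
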