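"""Delaunay neighbor graphs on cell centroids, with Euclidean edge weights.

The graph G = (V, E) has one node per cell, carrying the cell's categorical
attribute (phenotype or tumor state); edges come from a Delaunay triangulation
of the centroids and are weighted by the Euclidean distance in microns.
Radius queries (fixed-radius neighbor lists) are provided for the
neighborhood-composition and proximity analyses.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree


class GraphBuildError(ValueError):
    """Too few or degenerate input points for triangulation."""


@dataclasses.dataclass
class SpatialGraph:
    """Delaunay graph on a cell subset.

    ``node_ids``: cell ids in node order; ``coords``: (n, 2) micron
    coordinates; ``attributes``: categorical label per node (the entropy
    attribute c_j); ``edges``: (m, 2) int array of node-index pairs with
    i < j; ``weights``: Euclidean length of each edge (d_ij, microns).
    """

    node_ids: np.ndarray
    coords: np.ndarray
    attributes: np.ndarray
    edges: np.ndarray
    weights: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree k_i."""
        deg = np.zeros(self.n_nodes, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        """Adjacency as a list of neighbor-index arrays (sorted)."""
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return [np.array(sorted(nb), dtype=int) for nb in adj]

    def to_edge_table(self) -> pd.DataFrame:
        """Edge list as (source, target, weight) using cell ids."""
        return pd.DataFrame({
            "source": self.node_ids[self.edges[:, 0]],
            "target": self.node_ids[self.edges[:, 1]],
            "weight": self.weights,
        })


def build_delaunay_graph(cells, attribute: str,
                         max_edge: float | None = None) -> SpatialGraph:
    """Triangulate cell centroids and return the attribute-labelled graph.

    Parameters
    ----------
    cells:
        A :class:`~melspat.core_io.CellTable` or a DataFrame with columns
        ``cell_id``, ``x``, ``y`` and the attribute column.
    attribute:
        Name of the categorical label column to attach to nodes.
    max_edge:
        If set, edges longer than this (microns) are dropped after
        triangulation; the graph may then disconnect and isolated nodes can
        appear.
    """
    df = getattr(cells, "data", cells)
    if attribute not in df.columns:
        raise GraphBuildError(f"attribute column {attribute!r} not in cell table")
    attrs = df[attribute].to_numpy()
    if pd.isna(attrs).any():
        raise GraphBuildError(f"attribute {attribute!r} missing on some cells")
    pts = df[["x", "y"]].to_numpy(float)
    n = len(pts)
    if n < 3:
        raise GraphBuildError(f"need >= 3 cells for a Delaunay graph, got {n}")
    pts = _deduplicate(pts)
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # QhullError on collinear input
        raise GraphBuildError(f"degenerate geometry (collinear points?): {exc}")
    if tri.simplices.size == 0:
        raise GraphBuildError("degenerate geometry: no triangles produced")
    edges = _simplex_edges(tri.simplices)
    weights = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    if max_edge is not None:
        keep = weights <= max_edge
        edges, weights = edges[keep], weights[keep]
    return SpatialGraph(
        node_ids=df["cell_id"].to_numpy(),
        coords=pts,
        attributes=attrs,
        edges=edges,
        weights=weights,
    )


def radius_neighbors(cells, r: float) -> list[np.ndarray]:
    """Fixed-radius neighbor lists (d <= r, focal cell excluded).

    Returns one array of row positions per cell, in input order.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    df = getattr(cells, "data", cells)
    pts = df[["x", "y"]].to_numpy(float)
    tree = cKDTree(pts)
    lists = tree.query_ball_point(pts, r)
    return [np.array(sorted(set(nb) - {i}), dtype=int)
            for i, nb in enumerate(lists)]


def _deduplicate(pts: np.ndarray) -> np.ndarray:
    """Perturb exactly-coincident points by 1e-6 um so qhull sees distinct sites."""
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True,
                                   return_counts=True)
    if (counts > 1).any():
        warnings.warn("coincident cell centroids perturbed by 1e-6 um",
                      stacklevel=2)
        pts = pts.copy()
        rng = np.random.default_rng(0)
        for grp in np.flatnonzero(counts > 1):
            idx = np.flatnonzero(inverse == grp)[1:]
            pts[idx] += rng.normal(scale=1e-6, size=(len(idx), 2))
    return pts


def _simplex_edges(simplices: np.ndarray) -> np.ndarray:
    pairs = np.concatenate([simplices[:, [0, 1]], simplices[:, [1, 2]],
                            simplices[:, [0, 2]]])
    pairs.sort(axis=1)
    return np.unique(pairs, axis=0)
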