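"""Recurrent cellular neighborhoods (RCN) and their meta-groups (RCNG).

Each phenotyped cell's local neighborhood is summarized as the composition of
phenotypes among its radius-r neighbors (default r = 15 um, the 50-pixel query
of a 0.3 um/px acquisition).  Composition rows (frequencies, not counts, so
that local density does not dominate) are clustered with k-means into RCNs
(default k = 25); RCN centroids are then agglomeratively grouped into RCNGs
(default g = 11) by correlation similarity of their compositions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .entropy import ComparisonResult, compare_groups
from .spatial_graph import radius_neighbors


@dataclasses.dataclass
class NeighborhoodMatrix:
    """Per-cell neighbor-phenotype counts and frequencies within radius r.

    ``counts``/``frequencies``: DataFrames indexed like the cell table, one
    column per phenotype.  Isolated cells (no neighbor within r) are flagged
    and carry all-zero frequency rows; they are excluded from clustering.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    r: float
    isolated: pd.Series

    @property
    def phenotypes(self) -> list[str]:
        return list(self.counts.columns)


@dataclasses.dataclass
class RCNModel:
    """k-means neighborhood clustering: centroids, labels, RCN -> RCNG map."""

    k: int
    centroids: pd.DataFrame        #: k x phenotype frequency vectors
    labels: pd.Series              #: per-cell RCN id (-1 for isolated cells)
    seed: int
    inertia: float
    rcng_map: dict[int, int] | None = None

    @property
    def g(self) -> int | None:
        return len(set(self.rcng_map.values())) if self.rcng_map else None

    def rcng_labels(self) -> pd.Series:
        """Per-cell RCNG id (-1 for isolated cells)."""
        if self.rcng_map is None:
            raise ValueError("group_rcns has not been applied to this model")
        mapping = dict(self.rcng_map)
        mapping[-1] = -1
        return self.labels.map(mapping).rename("rcng")


def neighborhood_composition(cells, r: float = 15.0) -> NeighborhoodMatrix:
    """Count each phenotype among every cell's radius-r neighbors (focal
    cell excluded; inclusion uses d <= r)."""
    df = getattr(cells, "data", cells)
    if "phenotype" not in df.columns:
        raise ValueError("cell table has no phenotype column")
    phenos = pd.Categorical(df["phenotype"])
    categories = list(phenos.categories)
    codes = np.asarray(phenos.codes)
    counts = np.zeros((len(df), len(categories)), dtype=int)
    for i, nb in enumerate(radius_neighbors(df, r)):
        if len(nb):
            counts[i] = np.bincount(codes[nb], minlength=len(categories))
    totals = counts.sum(axis=1)
    isolated = totals == 0
    freqs = np.zeros_like(counts, dtype=float)
    nz = ~isolated
    freqs[nz] = counts[nz] / totals[nz, None]
    idx = df.index
    return NeighborhoodMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=categories),
        frequencies=pd.DataFrame(freqs, index=idx, columns=categories),
        r=r,
        isolated=pd.Series(isolated, index=idx, name="isolated"))


def cluster_rcn(matrix: NeighborhoodMatrix, k: int = 25,
                seed: int = 0, n_init: int = 10) -> RCNModel:
    """k-means on neighborhood frequency rows (non-isolated cells only)."""
    X = matrix.frequencies.loc[~matrix.isolated].to_numpy()
    n_distinct = len(np.unique(X, axis=0))
    if not 1 <= k <= n_distinct:
        raise ValueError(
            f"k must lie in [1, {n_distinct}] (distinct rows), got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = pd.Series(-1, index=matrix.frequencies.index, name="rcn")
    labels.loc[~matrix.isolated] = km.labels_
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.phenotypes)
    return RCNModel(k=k, centroids=centroids, labels=labels, seed=seed,
                    inertia=float(km.inertia_))


def select_k_elbow(matrix: NeighborhoodMatrix, k_range,
                   seed: int = 0, n_init: int = 5
                   ) -> tuple[int | None, pd.DataFrame]:
    """Elbow heuristic on the k-means inertia curve.

    The elbow is the k maximizing the perpendicular distance to the chord
    joining the curve's endpoints.  Returns ``(k, curve)``; ``k`` is None with
    a "no elbow" status column when the curve is non-decreasing.
    """
    k_range = sorted(k_range)
    if len(k_range) < 3:
        raise ValueError("k_range must contain at least 3 values")
    X = matrix.frequencies.loc[~matrix.isolated].to_numpy()
    inertia = [float(KMeans(n_clusters=k, n_init=n_init,
                            random_state=seed).fit(X).inertia_)
               for k in k_range]
    curve = pd.DataFrame({"k": k_range, "inertia": inertia})
    if not np.any(np.diff(inertia) < 0):
        curve["status"] = "no elbow"
        return None, curve
    # perpendicular distance from each point to the endpoint chord
    p0 = np.array([k_range[0], inertia[0]])
    p1 = np.array([k_range[-1], inertia[-1]])
    # normalize axes so the heuristic is scale-free
    span = np.array([k_range[-1] - k_range[0],
                     max(inertia[0] - inertia[-1], 1e-300)])
    q0, q1 = p0 / span, p1 / span
    pts = np.column_stack([np.array(k_range), np.array(inertia)]) / span
    chord = q1 - q0
    chord /= np.linalg.norm(chord)
    rel = pts - q0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    curve["chord_distance"] = dist
    return int(k_range[int(np.argmax(dist))]), curve


def group_rcns(model: RCNModel, g: int = 11) -> RCNModel:
    """Group the k RCN centroids into g RCNGs by average-linkage clustering
    with correlation distance; returns the model with ``rcng_map`` filled."""
    if not 1 <= g <= model.k:
        raise ValueError(f"g must lie in [1, {model.k}], got {g}")
    if g == model.k:
        model.rcng_map = {i: i for i in range(model.k)}
        return model
    C = model.centroids.to_numpy()
    if model.k == 1 or g == 1:
        model.rcng_map = {i: 0 for i in range(model.k)}
        return model
    Z = linkage(C, method="average", metric="correlation")
    flat = fcluster(Z, t=g, criterion="maxclust")
    model.rcng_map = {i: int(flat[i]) - 1 for i in range(model.k)}
    return model


def rcn_abundance(cells, group_col: str, label_col: str = "rcng"
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group RCNG proportion table plus pairwise rank-sum comparisons.

    ``cells`` must carry ``label_col`` (RCN or RCNG ids) and ``group_col``
    (region / branch / specimen).  Proportions are over non-isolated cells and
    sum to 1 per group.  Every RCNG is compared between every pair of groups
    by a Mann-Whitney test on per-specimen proportions when a ``specimen_id``
    column is present (otherwise the comparison table is empty).
    """
    df = getattr(cells, "data", cells)
    sub = df[df[label_col] >= 0]
    table = (sub.groupby([group_col, label_col]).size()
             .unstack(fill_value=0))
    table = table.div(table.sum(axis=1), axis=0)
    comparisons = []
    if "specimen_id" in df.columns and sub["specimen_id"].nunique() >= 3:
        per_spec = (sub.groupby([group_col, "specimen_id", label_col]).size()
                    .unstack(fill_value=0))
        per_spec = per_spec.div(per_spec.sum(axis=1), axis=0)
        groups = list(table.index)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                a_df = per_spec.loc[groups[gi]]
                b_df = per_spec.loc[groups[gj]]
                if len(a_df) < 3 or len(b_df) < 3:
                    continue
                for lab in table.columns:
                    res = compare_groups(a_df[lab], b_df[lab], test="rank_sum")
                    comparisons.append({
                        "group_a": groups[gi], "group_b": groups[gj],
                        label_col: lab, "statistic": res.statistic,
                        "pvalue": res.pvalue, "status": res.status})
    return table, pd.DataFrame(comparisons)
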