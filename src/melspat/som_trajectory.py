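"""SOM metagene portraits and the correlation spanning tree over microregions.

Genes are the observations: each gene's normalized expression profile across
microregions (samples) is mapped onto a 2-D self-organizing map (default
30 x 30 units, hence 900 metagenes).  Each unit's codebook vector — the
*metagene* — is a prototype expression profile shared by the genes mapped to
it.  A sample's *portrait* is the grid image of all metagene values for that
sample; mean and difference portraits summarize sample groups.  *Cluster
areas* are connected patches of units overexpressed (min-max scaled value at
or above a threshold, default 0.95) in some sample.  Finally, microregions are
arranged into a *correlation spanning tree* (CST): the minimum spanning tree
of 1 - Pearson correlation between their metagene profiles, decomposed into
branches at nodes of degree >= 3.

The SOM is trained in batch mode from a PCA-plane initialization with a
Gaussian neighborhood whose radius decays from half the grid diameter to 1,
so training is fully deterministic and reproducible.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label

from .core_io import ExpressionMatrix


class TrainingError(ValueError):
    pass


@dataclasses.dataclass
class SOMModel:
    """Trained SOM codebook on a fixed grid.

    ``codebook``: (rows*cols) x n_samples matrix of metagenes (unit u's
    prototype profile over samples); ``bmu``: per-gene best-matching unit
    index; ``quantization_errors``: mean gene-to-BMU distance per epoch.
    """

    grid: tuple[int, int]
    codebook: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    bmu: np.ndarray
    seed: int
    quantization_errors: list[float]

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def n_metagenes(self) -> int:
        return self.n_units

    def unit_coords(self) -> np.ndarray:
        """(row, col) of every unit, in codebook order."""
        rows, cols = self.grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])


@dataclasses.dataclass
class ClusterAreas:
    """Connected overexpression patches on the SOM grid."""

    threshold: float
    flags: pd.DataFrame            #: units x samples overexpression flags
    cluster_of_unit: np.ndarray    #: cluster id per unit (0 = unflagged)
    clusters: pd.DataFrame         #: per cluster: units, size, enriched samples


@dataclasses.dataclass
class CorrelationTree:
    """MST over microregions with edge weight 1 - Pearson r."""

    graph: nx.Graph
    branch_labels: dict[str, str] | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def to_edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"source": u, "target": v, "weight": d["weight"],
              "correlation": 1.0 - d["weight"]}
             for u, v, d in self.graph.edges(data=True)])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log10(x+1), quantile normalization across samples, gene-wise centering.

    Returns a genes x samples DataFrame.  Quantile normalization replaces each
    sample's sorted values with the mean sorted profile (ties averaged), so
    all per-sample value distributions become identical.
    """
    X = matrix.values.to_numpy(float).T      # genes x samples
    X = np.log10(X + 1.0)
    X = _quantile_normalize(X)
    X = X - X.mean(axis=1, keepdims=True)
    return pd.DataFrame(X, index=matrix.gene_ids, columns=matrix.microregion_ids)


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Columns (samples) forced to share the mean sorted profile; tied values
    within a column receive the mean of the reference values at their ranks."""
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    from scipy.stats import rankdata
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return out


# ---------------------------------------------------------------------------
# SOM training
# ---------------------------------------------------------------------------

def train_som(normalized: pd.DataFrame, grid: tuple[int, int] = (30, 30),
              seed: int = 0, n_epochs: int = 20,
              sigma_final: float = 1.0) -> SOMModel:
    """Batch-train a SOM on gene profiles (genes x samples input).

    PCA-plane initialization (codebook spanned by the first two principal
    components of the gene cloud) followed by ``n_epochs`` batch updates with
    a Gaussian neighborhood decaying exponentially from half the grid diameter
    to ``sigma_final``.  Deterministic: the same input and grid always yield
    the same codebook.
    """
    X = normalized.to_numpy(float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise TrainingError("SOM needs at least 2 samples")
    rows, cols = grid
    n_units = rows * cols
    if n_genes < 2 * n_units:
        import warnings
        warnings.warn(f"only {n_genes} genes for {n_units} SOM units; "
                      "metagenes will be weakly supported", stacklevel=2)

    codebook = _pca_plane_init(X, rows, cols)
    unit_rc = np.column_stack(np.unravel_index(np.arange(n_units),
                                               (rows, cols))).astype(float)
    # squared grid distances between all unit pairs
    d2 = ((unit_rc[:, None, :] - unit_rc[None, :, :]) ** 2).sum(-1)
    sigma0 = max(np.hypot(rows - 1, cols - 1) / 2.0, sigma_final)
    qes: list[float] = []
    bmu = np.zeros(n_genes, dtype=int)
    for epoch in range(n_epochs):
        sigma = sigma0 * (sigma_final / sigma0) ** (epoch / max(n_epochs - 1, 1))
        dist = _pairwise_sq(X, codebook)
        bmu = np.argmin(dist, axis=1)
        qes.append(float(np.sqrt(dist[np.arange(n_genes), bmu]).mean()))
        h = np.exp(-d2[:, bmu] / (2.0 * sigma ** 2))   # units x genes
        denom = h.sum(axis=1, keepdims=True)
        codebook = (h @ X) / np.where(denom > 0, denom, 1.0)
    dist = _pairwise_sq(X, codebook)
    bmu = np.argmin(dist, axis=1)
    qes.append(float(np.sqrt(dist[np.arange(n_genes), bmu]).mean()))
    return SOMModel(grid=grid, codebook=codebook,
                    sample_ids=list(normalized.columns),
                    gene_ids=list(normalized.index),
                    bmu=bmu, seed=seed, quantization_errors=qes)


def train_som_per_batch(matrix: ExpressionMatrix,
                        grid: tuple[int, int] = (30, 30), seed: int = 0,
                        batch_col: str = "batch",
                        **kwargs) -> dict[str, SOMModel]:
    """Fit one SOM per batch label (preprocessing done within each batch),
    for datasets where a shared fit would be dominated by batch effects."""
    if batch_col not in matrix.mr_metadata.columns:
        raise TrainingError(f"metadata has no {batch_col!r} column")
    models: dict[str, SOMModel] = {}
    for batch, meta in matrix.mr_metadata.groupby(batch_col):
        sub = ExpressionMatrix(matrix.values.loc[meta.index], meta)
        models[str(batch)] = train_som(preprocess_expression(sub),
                                       grid=grid, seed=seed, **kwargs)
    return models


def _pca_plane_init(X: np.ndarray, rows: int, cols: int) -> np.ndarray:
    mean = X.mean(axis=0)
    Xc = X - mean
    # deterministic SVD with sign convention: largest |loading| positive
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(min(2, vt.shape[0])):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    scale = s / max(np.sqrt(X.shape[0] - 1), 1.0)
    g1 = (np.linspace(-1, 1, rows) if rows > 1 else np.zeros(1))
    g2 = (np.linspace(-1, 1, cols) if cols > 1 else np.zeros(1))
    rr, cc = np.meshgrid(g1, g2, indexing="ij")
    codebook = mean[None, :] + \
        rr.ravel()[:, None] * scale[0] * vt[0][None, :]
    if vt.shape[0] > 1:
        codebook = codebook + cc.ravel()[:, None] * scale[1] * vt[1][None, :]
    return codebook


def _pairwise_sq(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances genes x units, clipped at 0."""
    d = (X ** 2).sum(1)[:, None] + (C ** 2).sum(1)[None, :] - 2.0 * X @ C.T
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# portraits
# ---------------------------------------------------------------------------

def sample_portrait(model: SOMModel, sample: str) -> np.ndarray:
    """Grid image of all metagene values for one sample."""
    if sample not in model.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    j = model.sample_ids.index(sample)
    return model.codebook[:, j].reshape(model.grid)


def group_portrait(model: SOMModel, samples) -> np.ndarray:
    """Element-wise mean portrait of a sample group."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample group")
    return np.mean([sample_portrait(model, s) for s in samples], axis=0)


def difference_portrait(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    return np.asarray(p1) - np.asarray(p2)


# ---------------------------------------------------------------------------
# overexpression cluster areas
# ---------------------------------------------------------------------------

def overexpression_clusters(model: SOMModel,
                            threshold: float = 0.95) -> ClusterAreas:
    """Connected patches of units overexpressed in some sample.

    Each metagene profile is min-max scaled over samples; a unit is flagged
    for sample s when its scaled value is >= threshold (constant profiles are
    never flagged).  Connected components (4-connectivity) of the union of
    flagged units form the cluster areas.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    C = model.codebook
    lo = C.min(axis=1, keepdims=True)
    hi = C.max(axis=1, keepdims=True)
    span = hi - lo
    nonconstant = span[:, 0] > 0
    scaled = np.zeros_like(C)
    scaled[nonconstant] = (C[nonconstant] - lo[nonconstant]) / span[nonconstant]
    flags = (scaled >= threshold) & nonconstant[:, None]
    union = flags.any(axis=1).reshape(model.grid)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labelled, n_clusters = cc_label(union, structure=structure)
    cluster_of_unit = labelled.ravel()
    rows = []
    for cid in range(1, n_clusters + 1):
        units = np.flatnonzero(cluster_of_unit == cid)
        enriched = [model.sample_ids[j]
                    for j in np.flatnonzero(flags[units].any(axis=0))]
        rows.append({"cluster_id": cid, "n_units": len(units),
                     "units": units.tolist(), "enriched_samples": enriched})
    return ClusterAreas(
        threshold=threshold,
        flags=pd.DataFrame(flags, columns=model.sample_ids),
        cluster_of_unit=cluster_of_unit,
        clusters=pd.DataFrame(rows,
                              columns=["cluster_id", "n_units", "units",
                                       "enriched_samples"]))


# ---------------------------------------------------------------------------
# correlation spanning tree
# ---------------------------------------------------------------------------

def correlation_spanning_tree(profiles: pd.DataFrame) -> CorrelationTree:
    """MST over microregions with distance 1 - Pearson r of metagene profiles.

    ``profiles``: microregions x metagenes (rows are nodes).  Ties in edge
    weight are broken lexicographically by node-id pair, so the tree is
    deterministic.  A constant profile has undefined correlations and raises.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 microregions")
    X = profiles.to_numpy(float)
    stds = X.std(axis=1)
    if (stds == 0).any():
        bad = [profiles.index[i] for i in np.flatnonzero(stds == 0)]
        raise ValueError(f"constant metagene profile(s): {bad}")
    R = np.corrcoef(X)
    ids = [str(i) for i in profiles.index]
    G = nx.Graph()
    G.add_nodes_from(ids)
    order = sorted((min(ids[i], ids[j]), max(ids[i], ids[j]), i, j)
                   for i in range(len(ids)) for j in range(i + 1, len(ids)))
    for u, v, i, j in order:   # lexicographic insertion -> stable tie-break
        G.add_edge(u, v, weight=float(1.0 - R[i, j]))
    mst = nx.minimum_spanning_tree(G, algorithm="kruskal")
    return CorrelationTree(graph=mst)


def decompose_branches(tree: CorrelationTree,
                       override: dict[str, str] | None = None,
                       n_branches: int | None = None) -> dict[str, str]:
    """Label tree nodes by branch.

    Default (``n_branches=None``): branch points are nodes of degree >= 3;
    removing them splits the tree into maximal paths (branches), labelled
    ``branch_1``, ``branch_2``, ... in order of their smallest node id.
    Branch points themselves are labelled ``branch_point``.  A path graph
    yields a single branch.

    ``n_branches=k`` instead applies the partitioned-tree reading used when a
    CST is interpreted as a small number of branches: the k-1 heaviest tree
    edges are removed (ties broken lexicographically) and each remaining
    component becomes one branch — single-linkage clustering on the tree.

    ``override`` maps node -> label and wins over the automatic decomposition
    (the branch reading of a CST is partly interpretive).
    """
    G = tree.graph
    labels: dict[str, str] = {}
    if n_branches is not None:
        if not 1 <= n_branches <= G.number_of_nodes():
            raise ValueError(f"n_branches must lie in [1, {G.number_of_nodes()}]")
        ranked = sorted(G.edges(data=True),
                        key=lambda e: (-e[2]["weight"], min(e[0], e[1]),
                                       max(e[0], e[1])))
        pruned = G.copy()
        pruned.remove_edges_from([(u, v) for u, v, _ in
                                  ranked[:n_branches - 1]])
        components = sorted(nx.connected_components(pruned), key=min)
        for i, comp in enumerate(components, start=1):
            for n in comp:
                labels[n] = f"branch_{i}"
    else:
        hubs = {n for n in G.nodes if G.degree(n) >= 3}
        rest = G.subgraph(n for n in G.nodes if n not in hubs)
        components = sorted(nx.connected_components(rest), key=min)
        for i, comp in enumerate(components, start=1):
            for n in comp:
                labels[n] = f"branch_{i}"
        for n in hubs:
            labels[n] = "branch_point"
    if override:
        labels.update(override)
    tree.branch_labels = labels
    return labels


def metagene_profiles(model: SOMModel) -> pd.DataFrame:
    """Microregions x metagenes matrix (the codebook transposed), the input
    to :func:`correlation_spanning_tree`."""
    return pd.DataFrame(model.codebook.T, index=model.sample_ids,
                        columns=[f"mg{u}" for u in range(model.n_units)])
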