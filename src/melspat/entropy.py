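"""Local Shannon entropy and the region-level spatial entropy statistic.

Tumor-cell intermixing is quantified on a Delaunay graph of tumor cells, with
each node carrying a categorical attribute c_j (tumor state or phenotype).

*Local* entropy of cell i is the Shannon entropy (bits) of the attribute
frequencies among its Delaunay neighbors (the focal cell itself excluded by
default).

The *region-level* spatial entropy augments the classical Shannon term for
each attribute l with a prefactor that grows with intermixing strength and
shrinks with the distance between heterotypic neighbors:

    M_i,l = sum_j I(c_j != l)              (heterotypic neighbor count of cell i)
    D_i,l = sum_j d_ij I(c_j != l)         (their summed distance, microns)
    Mbar_l, Dbar_l = means of M_i,l, D_i,l over the n_l cells with attribute l
    p_l = n_l / N

    H = -alpha * sum_l (Mbar_l / Dbar_l) * p_l * log2(p_l)

An attribute whose members have no heterotypic neighbors contributes 0 (the
M -> 0 limit of Mbar/Dbar).  With alpha dimensionless, H carries units of
bits per micron: doubling all coordinates halves H.  The sum is negated so
that H >= 0; the raw signed sum is also reported.

Group comparisons (Mann-Whitney U rank test for location, Levene/Brown-
Forsythe for variance) delegate to scipy.stats.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .spatial_graph import GraphBuildError, SpatialGraph, build_delaunay_graph


@dataclasses.dataclass
class EntropyResult:
    """Region-level spatial entropy with its per-attribute audit components."""

    region_id: str | None
    n_cells: int
    L: int                       #: number of attributes present
    components: pd.DataFrame     #: per attribute: n_l, p_l, M_bar, D_bar, term
    alpha: float
    H: float                     #: non-negative spatial entropy (bits / um)
    H_signed: float              #: the un-negated sum as printed in the formula
    local_entropy: pd.Series     #: per-cell local Shannon entropy, bits
    status: str = "ok"           #: "ok" or "not-computable"

    @classmethod
    def not_computable(cls, region_id: str | None, n_cells: int) -> "EntropyResult":
        return cls(region_id=region_id, n_cells=n_cells, L=0,
                   components=pd.DataFrame(
                       columns=["n_l", "p_l", "M_bar", "D_bar", "term"]),
                   alpha=np.nan, H=np.nan, H_signed=np.nan,
                   local_entropy=pd.Series(dtype=float),
                   status="not-computable")


@dataclasses.dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    test: str
    status: str = "ok"


def local_shannon_entropy(graph: SpatialGraph,
                          include_focal: bool = False) -> pd.Series:
    """Per-cell Shannon entropy (bits) of neighbor attribute frequencies.

    Isolated nodes (possible only after max_edge pruning) get entropy 0; their
    ids are attached as ``result.attrs["isolated"]``.
    """
    attrs = graph.attributes
    ent = np.zeros(graph.n_nodes)
    isolated = []
    for i, nb in enumerate(graph.neighbor_lists()):
        labels = attrs[nb]
        if include_focal:
            labels = np.append(labels, attrs[i])
        if len(labels) == 0:
            isolated.append(graph.node_ids[i])
            continue
        _, counts = np.unique(labels, return_counts=True)
        f = counts / counts.sum()
        ent[i] = -(f * np.log2(f)).sum()
    out = pd.Series(ent, index=pd.Index(graph.node_ids, name="cell_id"),
                    name="local_entropy")
    out.attrs["isolated"] = isolated
    return out


def spatial_entropy(graph: SpatialGraph, alpha: float = 1.0,
                    region_id: str | None = None) -> EntropyResult:
    """Region-level spatial entropy H with all audit components."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if graph.n_nodes == 0:
        raise GraphBuildError("empty graph")
    attrs = graph.attributes
    n = graph.n_nodes
    levels, inv = np.unique(attrs, return_inverse=True)

    # per-cell heterotypic neighbor count and distance sum
    M_i = np.zeros(n)
    D_i = np.zeros(n)
    if len(graph.edges):
        a, b = graph.edges[:, 0], graph.edges[:, 1]
        hetero = inv[a] != inv[b]
        np.add.at(M_i, a[hetero], 1.0)
        np.add.at(M_i, b[hetero], 1.0)
        np.add.at(D_i, a[hetero], graph.weights[hetero])
        np.add.at(D_i, b[hetero], graph.weights[hetero])

    rows = []
    H_signed = 0.0
    for l_idx, level in enumerate(levels):
        members = inv == l_idx
        n_l = int(members.sum())
        p_l = n_l / n
        M_bar = float(M_i[members].mean())
        D_bar = float(D_i[members].mean())
        # M_bar == 0 forces D_bar == 0; the attribute then contributes 0
        prefactor = M_bar / D_bar if M_bar > 0 else 0.0
        plogp = p_l * np.log2(p_l) if p_l > 0 else 0.0
        term = alpha * prefactor * plogp
        H_signed += term
        rows.append({"attribute": level, "n_l": n_l, "p_l": p_l,
                     "M_bar": M_bar, "D_bar": D_bar, "term": term})
    components = pd.DataFrame(rows).set_index("attribute")
    return EntropyResult(
        region_id=region_id, n_cells=n, L=len(levels), components=components,
        alpha=alpha, H=-H_signed, H_signed=H_signed,
        local_entropy=local_shannon_entropy(graph))


def entropy_by_region(cells, regions, attribute: str,
                      alpha: float = 1.0,
                      max_edge: float | None = None) -> list[EntropyResult]:
    """Spatial entropy per annotated region.

    For each region (polygons only; the epidermis reference is skipped), cells
    inside the polygon carrying a non-null ``attribute`` are selected, a fresh
    Delaunay graph is built on them, and :func:`spatial_entropy` computed.
    Regions with fewer than 3 such cells (or degenerate geometry) are returned
    with status ``"not-computable"``.
    """
    df = getattr(cells, "data", cells)
    if attribute not in df.columns:
        raise GraphBuildError(f"attribute column {attribute!r} not in cell table")
    labelled = df[df[attribute].notna()]
    results = []
    for region in regions:
        if region.role == "epidermis_reference":
            continue
        inside = region.contains(labelled["x"].to_numpy(),
                                 labelled["y"].to_numpy())
        sub = labelled[inside]
        if len(sub) < 3:
            results.append(EntropyResult.not_computable(region.region_id, len(sub)))
            continue
        try:
            graph = build_delaunay_graph(sub, attribute, max_edge=max_edge)
        except GraphBuildError:
            results.append(EntropyResult.not_computable(region.region_id, len(sub)))
            continue
        results.append(spatial_entropy(graph, alpha=alpha,
                                       region_id=region.region_id))
    return results


def entropy_table(results: list[EntropyResult]) -> pd.DataFrame:
    """Flatten per-region results into one row per region."""
    rows = []
    for r in results:
        rows.append({"region_id": r.region_id, "n_cells": r.n_cells, "L": r.L,
                     "H": r.H, "status": r.status})
    return pd.DataFrame(rows)


def compare_groups(values_a, values_b, test: str = "rank_sum",
                   alternative: str = "two-sided",
                   center: str = "median") -> ComparisonResult:
    """Compare two samples of entropy values.

    ``test="rank_sum"``: two-sample Mann-Whitney U; the exact null
    distribution is enumerated when min(n, m) <= 8 and there are no ties,
    otherwise the tie-corrected normal approximation is used.
    ``test="variance"``: Levene's test on absolute deviations from the group
    center (default median, i.e. the Brown-Forsythe variant; ``center="mean"``
    gives the classical form).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "rank_sum":
        if min(len(a), len(b)) < 3:
            raise ValueError("rank_sum needs >= 3 values per group")
        if len(np.unique(np.concatenate([a, b]))) == 1:
            return ComparisonResult(np.nan, np.nan, test, status="degenerate-data")
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
            else "asymptotic"
        stat, p = stats.mannwhitneyu(a, b, alternative=alternative,
                                     method=method)
        return ComparisonResult(float(stat), float(p), test)
    if test == "variance":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("variance test needs >= 2 values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return ComparisonResult(0.0, np.nan, test, status="degenerate-data")
        stat, p = stats.levene(a, b, center=center)
        return ComparisonResult(float(stat), float(p), test)
    raise ValueError(f"unknown test {test!r}; expected 'rank_sum' or 'variance'")
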