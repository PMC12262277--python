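"""Invasion bands and comparative proximity analysis.

Invasion bands decompose a section into fixed-thickness strips (default
0.2 mm) by distance from the annotated epidermis, so spatial statistics can be
tracked against invasion depth.  Comparative proximity analysis contrasts the
radius-r cellular surroundings (default 15 um) of two focal tumor states —
e.g. SOX10+ MART1- (dedifferentiated) vs SOX10+ MART1+ (melanocytic) — with
per-phenotype rank-sum tests and Benjamini-Hochberg correction across
phenotypes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import false_discovery_control

from .entropy import EntropyResult, compare_groups, spatial_entropy
from .spatial_graph import GraphBuildError, build_delaunay_graph


class ContractError(ValueError):
    pass


@dataclasses.dataclass
class BandAssignment:
    """Per-cell epidermis distance and invasion-band index.

    Band k covers distances in the half-open interval [k*w, (k+1)*w); a cell
    exactly on a band boundary belongs to the deeper band.
    """

    distances: pd.Series   #: microns to the nearest point of the reference
    bands: pd.Series       #: integer band index, floor(distance / band_width)
    band_width: float


@dataclasses.dataclass
class ProximityProfile:
    """Radius-r surroundings of two focal tumor states, compared per phenotype."""

    focal_states: tuple[str, str]
    r: float
    per_cell_counts: pd.DataFrame    #: focal cells x phenotypes (+ state, region)
    region_means: pd.DataFrame       #: (state, region) x phenotype mean composition
    comparisons: pd.DataFrame        #: per phenotype: statistic, pvalue, qvalue
    status: str = "ok"


def distance_to_epidermis(cells, reference) -> pd.Series:
    """Euclidean distance (microns) from each centroid to the nearest point of
    the epidermis reference geometry (0 inside a reference polygon)."""
    if reference is None:
        raise ContractError("no epidermis reference geometry provided")
    geometry = getattr(reference, "geometry", reference)
    df = getattr(cells, "data", cells)
    pts = shapely.points(df[["x", "y"]].to_numpy(float))
    d = shapely.distance(geometry, pts)
    return pd.Series(d, index=df.index, name="epidermis_distance")


def assign_bands(distances, band_width: float = 200.0) -> BandAssignment:
    """Bin epidermis distances into invasion bands of the given thickness."""
    if band_width <= 0:
        raise ValueError(f"band_width must be positive, got {band_width}")
    d = pd.Series(distances, dtype=float)
    if (d < 0).any():
        raise ContractError("negative epidermis distances")
    bands = np.floor(d / band_width).astype(int)
    return BandAssignment(distances=d.rename("epidermis_distance"),
                          bands=bands.rename("band"),
                          band_width=band_width)


def entropy_by_band(cells, bands: BandAssignment, regions,
                    attribute: str, alpha: float = 1.0,
                    max_edge: float | None = None) -> list[EntropyResult]:
    """Spatial entropy per (region x band) subregion.

    Within each annotated region, cells carrying the attribute are split into
    disjoint invasion bands and :func:`~melspat.entropy.spatial_entropy` is
    computed for each band with >= 3 such cells; smaller subregions are
    reported not-computable.  Result region ids are ``"<region>/band<k>"``.
    """
    df = getattr(cells, "data", cells)
    if attribute not in df.columns:
        raise ContractError(f"attribute column {attribute!r} not in cell table")
    labelled = df[df[attribute].notna()]
    results = []
    for region in regions:
        if region.role == "epidermis_reference":
            continue
        inside = region.contains(labelled["x"].to_numpy(),
                                 labelled["y"].to_numpy())
        sub = labelled[inside]
        for band, band_cells in sub.groupby(bands.bands.reindex(sub.index)):
            rid = f"{region.region_id}/band{band}"
            if len(band_cells) < 3:
                results.append(EntropyResult.not_computable(rid, len(band_cells)))
                continue
            try:
                graph = build_delaunay_graph(band_cells, attribute,
                                             max_edge=max_edge)
            except GraphBuildError:
                results.append(EntropyResult.not_computable(rid, len(band_cells)))
                continue
            results.append(spatial_entropy(graph, alpha=alpha, region_id=rid))
    return results


def proximity_profile(cells, focal_state_a: str, focal_state_b: str,
                      r: float = 15.0, group_col: str = "region_id"
                      ) -> ProximityProfile:
    """Compare the radius-r phenotype surroundings of two focal tumor states.

    For every focal cell of each state, phenotypes within r are counted
    (focal cell excluded; empty neighborhoods contribute zero rows).  Counts
    are averaged into compositions per (state, group); each phenotype is then
    compared between the two states with a two-sided rank-sum test on the
    per-group means, and p-values are Benjamini-Hochberg adjusted across
    phenotypes.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    df = getattr(cells, "data", cells)
    for col in ("tumor_state", "phenotype"):
        if col not in df.columns:
            raise ContractError(f"cell table lacks {col!r}")
    states = (focal_state_a, focal_state_b)
    focal_mask = df["tumor_state"].isin(states)
    if not focal_mask.any() or df.loc[focal_mask, "tumor_state"].nunique() < 2:
        empty = pd.DataFrame()
        return ProximityProfile(states, r, empty, empty, empty,
                                status="not-computable")
    phenos = pd.Categorical(df["phenotype"])
    categories = list(phenos.categories)
    codes = np.asarray(phenos.codes)
    pts = df[["x", "y"]].to_numpy(float)
    tree = cKDTree(pts)
    focal_idx = np.flatnonzero(focal_mask.to_numpy())
    counts = np.zeros((len(focal_idx), len(categories)), dtype=int)
    for row, i in enumerate(focal_idx):
        nb = [j for j in tree.query_ball_point(pts[i], r) if j != i]
        if nb:
            counts[row] = np.bincount(codes[nb], minlength=len(categories))
    per_cell = pd.DataFrame(counts, columns=categories,
                            index=df.index[focal_idx])
    per_cell["state"] = df.loc[per_cell.index, "tumor_state"]
    group = (df.loc[per_cell.index, group_col]
             if group_col in df.columns
             else df.loc[per_cell.index, "specimen_id"])
    per_cell["group"] = group

    region_means = (per_cell.groupby(["state", "group"], observed=True)
                    [categories].mean())
    lvl0 = region_means.index.get_level_values(0)
    rows = []
    for ph in categories:
        a = (region_means.xs(focal_state_a)[ph] if focal_state_a in lvl0
             else pd.Series(dtype=float))
        b = (region_means.xs(focal_state_b)[ph] if focal_state_b in lvl0
             else pd.Series(dtype=float))
        if len(a) < 3 or len(b) < 3:
            rows.append({"phenotype": ph, "statistic": np.nan,
                         "pvalue": np.nan, "status": "not-computable"})
            continue
        res = compare_groups(a, b, test="rank_sum")
        rows.append({"phenotype": ph, "statistic": res.statistic,
                     "pvalue": res.pvalue, "status": res.status})
    comparisons = pd.DataFrame(rows)
    valid = comparisons["pvalue"].notna()
    comparisons["qvalue"] = np.nan
    if valid.any():
        comparisons.loc[valid, "qvalue"] = false_discovery_control(
            comparisons.loc[valid, "pvalue"], method="bh")
    return ProximityProfile(states, r, per_cell, region_means, comparisons)


def nearest_neighbor_distances(cells, type_pairs,
                               label_col: str = "phenotype") -> pd.DataFrame:
    """Mean nearest-neighbor distance for each ordered (type_a, type_b) pair.

    For each cell of type A, the distance to the nearest cell of type B
    (excluding the cell itself when A == B); pairs whose types are absent, or
    A == B with a single cell, are reported not-computable.
    """
    df = getattr(cells, "data", cells)
    if label_col not in df.columns:
        raise ContractError(f"cell table lacks {label_col!r}")
    pts = df[["x", "y"]].to_numpy(float)
    labels = df[label_col].to_numpy()
    trees: dict[str, tuple[cKDTree, np.ndarray]] = {}

    def tree_for(t: str):
        if t not in trees:
            idx = np.flatnonzero(labels == t)
            trees[t] = (cKDTree(pts[idx]) if len(idx) else None, idx)
        return trees[t]

    rows = []
    for ta, tb in type_pairs:
        tree_a, idx_a = tree_for(ta)
        tree_b, idx_b = tree_for(tb)
        if tree_a is None or tree_b is None or (ta == tb and len(idx_a) < 2):
            rows.append({"type_a": ta, "type_b": tb, "mean_distance": np.nan,
                         "n": len(idx_a), "status": "not-computable"})
            continue
        if ta == tb:
            d, _ = tree_b.query(pts[idx_a], k=2)
            d = d[:, 1]
        else:
            d, _ = tree_b.query(pts[idx_a], k=1)
        rows.append({"type_a": ta, "type_b": tb,
                     "mean_distance": float(np.mean(d)), "n": len(idx_a),
                     "status": "ok"})
    return pd.DataFrame(rows)
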