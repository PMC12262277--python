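"""Synthetic tissue and expression generators.

The tissue simulator emulates a vertical section of primary melanoma skin:
an epidermal band at the top, a dermal compartment below it, tumor nests at
depth-dependent progression stages, clustered immune infiltrates, and small
perivascular endothelial clusters.  Cells are placed by compartment-specific
Poisson point processes with hard-core thinning (minimum spacing 4 um, so no
two nuclei coincide and Delaunay construction is well-posed).  Every cell
carries a hidden true phenotype and — for tumor cells — a true differentiation
state; marker intensities are drawn from per-marker two-component log-normal
models conditional on that truth, so gate-based phenotyping can be scored
against ground truth.

Tumor-state intermixing is controlled by ``theta``: each tumor cell copies its
nest's dominant state with probability 1 - theta and otherwise redraws its
state uniformly from the four-state set (melanocytic, transitional,
mesenchymal, NC-like).  ``theta = 0`` gives single-state nests (spatial
entropy 0); larger theta plants more heterotypic contacts.

The expression simulator draws microregion x gene negative-binomial counts
whose log-means follow a two-latent-factor structure (progression x
inflammation) with sparse gene loadings, mimicking how microregional
transcriptomes organize along a progression axis modulated by inflammatory
programs.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from .core_io import CellTable, ExpressionMatrix, RegionAnnotation
from .phenotyping import TUMOR_STATES, Gate, GateSet

#: (negative log-mean, negative sigma, positive log-mean, positive sigma, gate)
#: for each marker, in arbitrary fluorescence units.  Components are ~2.9 sigma
#: from the geometric-mean gate, i.e. well separated but not error-free.
DEFAULT_MARKER_MODEL: dict[str, tuple[float, float, float, float, float]] = {
    m: (np.log(100.0), 0.4, np.log(1000.0), 0.4, 316.0)
    for m in ("SOX10", "MART1", "SOX9", "NGFR", "CD45", "CD3",
              "CD163", "CD31", "panCK")
}

#: binarized truth pattern per phenotype/state: markers positive for the cell
_STATE_MARKERS = {
    "melanocytic": ("SOX10", "MART1"),
    "transitional": ("SOX10", "MART1", "SOX9"),
    "mesenchymal": ("SOX10", "SOX9"),
    "NC-like": ("SOX10", "NGFR"),
}
_PHENOTYPE_MARKERS = {
    "T cell": ("CD45", "CD3"),
    "macrophage": ("CD45", "CD163"),
    "endothelial": ("CD31",),
    "epithelial": ("panCK",),
    "stromal": (),
}


class CapacityError(ValueError):
    """Configured densities imply an infeasible number of cells."""


@dataclasses.dataclass
class TissueSimConfig:
    """Parameters of the marked-point-process tissue simulator.

    Densities are cells/mm^2; lengths are microns.  ``theta`` in [0, 1] is the
    per-cell probability of redrawing a tumor cell's state uniformly from the
    state set instead of copying the nest's dominant state; ``nest_thetas``
    overrides it per nest.
    """

    seed: int = 0
    field_size: tuple[float, float] = (1500.0, 1000.0)   # (width, height) um
    epidermis_depth: float = 100.0
    epidermis_density: float = 3000.0
    dermis_density: float = 1200.0
    nest_density: float = 6000.0
    n_nests: int = 6
    nest_radius: tuple[float, float] = (60.0, 120.0)
    rgp_depth: float = 300.0        # nests deeper than this (below epidermis) are VGP
    theta: float = 0.3
    nest_thetas: Sequence[float] | None = None
    n_immune_clusters: int = 8
    immune_cluster_size: float = 40.0     # mean cells per cluster
    immune_cluster_scale: float = 30.0    # Gaussian displacement sd, um
    macrophage_fraction: float = 0.3
    n_vessels: int = 5
    vessel_cells: float = 15.0
    vessel_scale: float = 10.0
    min_spacing: float = 4.0
    specimen_id: str = "SYN01"
    states: tuple[str, ...] = TUMOR_STATES
    marker_model: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MARKER_MODEL))

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if self.nest_thetas is not None:
            th = np.asarray(self.nest_thetas, dtype=float)
            if len(th) != self.n_nests:
                raise ValueError("nest_thetas must have one entry per nest")
            if ((th < 0) | (th > 1)).any():
                raise ValueError("nest_thetas must lie in [0, 1]")
        for name in ("epidermis_density", "dermis_density", "nest_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class ExpressionSimConfig:
    """Parameters of the two-latent-factor expression simulator."""

    seed: int = 0
    n_microregions: int = 60
    n_genes: int = 300
    module_fraction: float = 0.15   # of genes per loaded module (3 modules)
    loading_scale: float = 1.5
    baseline_log_mean: float = 4.0  # natural-log scale; exp(4) ~ 55 counts
    baseline_log_sd: float = 0.5
    dispersion: float = 0.3         # NB: var = mu + dispersion * mu^2
    n_batches: int = 1
    batch_sd: float = 0.3
    progression: Sequence[float] | None = None   # per-MR scores in [0, 1]
    inflammation: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10 (gene modules are needed)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("progression", "inflammation"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v, dtype=float)
                if len(arr) != self.n_microregions:
                    raise ValueError(f"{name} must have one score per microregion")
                if ((arr < 0) | (arr > 1)).any():
                    raise ValueError(f"{name} scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------

def _poisson_count(rng: np.random.Generator, density: float, area_um2: float) -> int:
    """Poisson cell count for a compartment (density in cells/mm^2)."""
    return int(rng.poisson(density * area_um2 / 1e6))


def _hardcore_thin(points: np.ndarray, min_spacing: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Matern-II style thinning: keep a point iff no kept point with higher
    random priority lies within min_spacing.  Returns indices kept."""
    n = len(points)
    if n == 0:
        return np.array([], dtype=int)
    priority = rng.permutation(n)
    order = np.argsort(priority)
    tree = cKDTree(points)
    pairs = tree.query_pairs(min_spacing, output_type="ndarray")
    conflicts: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        conflicts[a].append(b)
        conflicts[b].append(a)
    kept = np.zeros(n, dtype=bool)
    for i in order:
        if not any(kept[j] for j in conflicts[i]):
            kept[i] = True
    return np.flatnonzero(kept)


def _separated_centers(rng: np.random.Generator, n: int,
                       x_range: tuple[float, float],
                       y_range: tuple[float, float],
                       min_sep: float) -> np.ndarray:
    """Dart-throwing placement with a minimum center separation; the
    separation is relaxed by 20% whenever 200 consecutive throws fail, so
    placement always succeeds (annotated nests are spatially distinct, but a
    small field must not dead-lock the simulator)."""
    centers: list[np.ndarray] = []
    sep = min_sep
    fails = 0
    while len(centers) < n:
        cand = np.array([rng.uniform(*x_range), rng.uniform(*y_range)])
        if all(np.linalg.norm(cand - c) >= sep for c in centers):
            centers.append(cand)
            fails = 0
        else:
            fails += 1
            if fails >= 200:
                sep *= 0.8
                fails = 0
    return np.array(centers)


def simulate_tissue(config: TissueSimConfig,
                    t_cluster_nests: Sequence[int] | None = None
                    ) -> tuple[CellTable, list[RegionAnnotation], pd.DataFrame]:
    """Simulate a tissue section.

    Returns ``(cells, regions, truth)`` where ``truth`` holds, per cell, the
    hidden phenotype, tumor state, and nest id.  ``regions`` contains one
    circular polygon per nest (stage assigned by depth) and the epidermis
    reference polyline.  ``t_cluster_nests`` optionally pins each immune
    cluster to a nest (used by :func:`simulate_coupled_infiltrate`).
    """
    rng = np.random.default_rng(config.seed)
    W, H = config.field_size
    epi = config.epidermis_depth
    r_lo, r_hi = config.nest_radius

    exp_total = (config.epidermis_density * W * epi
                 + config.dermis_density * W * (H - epi)
                 + config.nest_density * config.n_nests * np.pi * r_hi ** 2) / 1e6
    if exp_total > 1e7:
        raise CapacityError(f"expected cell count {exp_total:.2e} exceeds 1e7")

    xs, ys, phenos, states, nests = [], [], [], [], []

    def emit(pts: np.ndarray, pheno: str | np.ndarray,
             state: str | None | np.ndarray = None, nest: int = -1) -> None:
        n = len(pts)
        if n == 0:
            return
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        phenos.append(np.full(n, pheno) if np.isscalar(pheno) or isinstance(pheno, str) else pheno)
        states.append(np.full(n, state, dtype=object) if not isinstance(state, np.ndarray) else state)
        nests.append(np.full(n, nest))

    # epidermis: keratinocyte-like band at the top
    n_epi = _poisson_count(rng, config.epidermis_density, W * epi)
    emit(np.column_stack([rng.uniform(0, W, n_epi), rng.uniform(0, epi, n_epi)]),
         "epithelial")

    # dermal stroma
    n_derm = _poisson_count(rng, config.dermis_density, W * (H - epi))
    emit(np.column_stack([rng.uniform(0, W, n_derm),
                          rng.uniform(epi, H, n_derm)]), "stromal")

    # tumor nests with depth-dependent stage and theta-mixed states
    nest_thetas = (np.asarray(config.nest_thetas, dtype=float)
                   if config.nest_thetas is not None
                   else np.full(config.n_nests, config.theta))
    nest_centers = _separated_centers(
        rng, config.n_nests, x_range=(r_hi, W - r_hi),
        y_range=(epi * 0.5, H - r_hi), min_sep=2.5 * r_hi)
    nest_radii = rng.uniform(r_lo, r_hi, config.n_nests)
    dominant = rng.integers(len(config.states), size=config.n_nests)
    regions: list[RegionAnnotation] = []
    for k in range(config.n_nests):
        cx, cy = nest_centers[k]
        R = nest_radii[k]
        n_cells = _poisson_count(rng, config.nest_density, np.pi * R ** 2)
        rad = R * np.sqrt(rng.uniform(size=n_cells))
        ang = rng.uniform(0, 2 * np.pi, n_cells)
        pts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
        redraw = rng.uniform(size=n_cells) < nest_thetas[k]
        state_idx = np.where(redraw,
                             rng.integers(len(config.states), size=n_cells),
                             dominant[k])
        emit(pts, "tumor", np.array(config.states, dtype=object)[state_idx],
             nest=k)
        depth = cy - epi
        stage = "MIS" if depth <= 0 else ("RGP" if depth <= config.rgp_depth
                                          else "VGP")
        regions.append(RegionAnnotation(
            region_id=f"nest_{k:02d}", geometry=Point(cx, cy).buffer(R * 1.1),
            stage=stage, role="histologic_region"))

    # clustered immune infiltrate (Thomas process)
    if t_cluster_nests is None:
        cluster_centers = np.column_stack([
            rng.uniform(0, W, config.n_immune_clusters),
            rng.uniform(epi, H, config.n_immune_clusters)])
    else:
        # pinned near the rim of the designated nests
        idx = np.asarray(t_cluster_nests, dtype=int)
        ang = rng.uniform(0, 2 * np.pi, len(idx))
        dist = nest_radii[idx] * rng.uniform(1.0, 1.6, len(idx))
        cluster_centers = nest_centers[idx] + \
            np.column_stack([dist * np.cos(ang), dist * np.sin(ang)])
        cluster_centers[:, 0] = np.clip(cluster_centers[:, 0], 0, W)
        cluster_centers[:, 1] = np.clip(cluster_centers[:, 1], epi, H)
    for cx, cy in cluster_centers:
        n_cells = rng.poisson(config.immune_cluster_size)
        pts = np.column_stack([cx, cy]) + \
            rng.normal(scale=config.immune_cluster_scale, size=(n_cells, 2))
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] <= W)
                & (pts[:, 1] >= 0) & (pts[:, 1] <= H))
        pts = pts[keep]
        is_mac = rng.uniform(size=len(pts)) < config.macrophage_fraction
        emit(pts, np.where(is_mac, "macrophage", "T cell"))

    # perivascular endothelial clusters
    for _ in range(config.n_vessels):
        cx = rng.uniform(0, W)
        cy = rng.uniform(epi, H)
        n_cells = rng.poisson(config.vessel_cells)
        pts = np.column_stack([cx, cy]) + \
            rng.normal(scale=config.vessel_scale, size=(n_cells, 2))
        emit(pts, "endothelial")

    pts = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    pheno = np.concatenate(phenos)
    state = np.concatenate(states)
    nest = np.concatenate(nests)
    keep = _hardcore_thin(pts, config.min_spacing, rng)
    pts, pheno, state, nest = pts[keep], pheno[keep], state[keep], nest[keep]

    intensities = _draw_intensities(rng, pheno, state, config.marker_model)
    markers = list(config.marker_model)
    data = pd.DataFrame({"cell_id": np.arange(len(pts)),
                         "specimen_id": config.specimen_id,
                         "x": pts[:, 0], "y": pts[:, 1]})
    for i, m in enumerate(markers):
        data[m] = intensities[:, i]
    cells = CellTable(data, markers)

    regions.append(RegionAnnotation(
        region_id="epidermis", geometry=LineString([(0, epi), (W, epi)]),
        stage=None, role="epidermis_reference"))
    truth = pd.DataFrame({"cell_id": np.arange(len(pts)),
                          "true_phenotype": pheno,
                          "true_state": state,
                          "nest_id": nest})
    return cells, regions, truth


def _draw_intensities(rng: np.random.Generator, pheno: np.ndarray,
                      state: np.ndarray, marker_model: dict) -> np.ndarray:
    markers = list(marker_model)
    positive = np.zeros((len(pheno), len(markers)), dtype=bool)
    for j, m in enumerate(markers):
        for ph, mk in _PHENOTYPE_MARKERS.items():
            if m in mk:
                positive[pheno == ph, j] = True
        for st, mk in _STATE_MARKERS.items():
            if m in mk:
                positive[(pheno == "tumor") & (state == st), j] = True
    out = np.empty_like(positive, dtype=float)
    for j, m in enumerate(markers):
        mu0, sd0, mu1, sd1, _ = marker_model[m]
        pos = positive[:, j]
        out[:, j] = np.where(pos,
                             rng.lognormal(mu1, sd1, len(pheno)),
                             rng.lognormal(mu0, sd0, len(pheno)))
    return out


def true_gates(config: TissueSimConfig) -> GateSet:
    """The simulator's true per-marker gates as a GateSet (min/max at the
    0.1/99.9 percentiles of the two-component mixture, fixed analytically)."""
    gates = []
    for m, (mu0, sd0, mu1, sd1, gate) in config.marker_model.items():
        vmin = float(np.exp(mu0 - 3.1 * sd0))
        vmax = float(np.exp(mu1 + 3.1 * sd1))
        gates.append(Gate(config.specimen_id, m, gate, vmin, vmax))
    return GateSet(gates)


def simulate_coupled_infiltrate(config: TissueSimConfig, coupling: float
                                ) -> tuple[CellTable, list[RegionAnnotation],
                                           pd.DataFrame]:
    """Tissue where immune clusters prefer high-theta (high-intermixing) nests.

    Each immune cluster is pinned near one nest; the nest is chosen with
    probability proportional to exp(coupling * theta_k).  ``coupling = 0``
    makes the choice uniform over nests, i.e. independent of theta.
    """
    if coupling < 0:
        raise ValueError(f"coupling must be >= 0, got {coupling}")
    if config.nest_thetas is None:
        config = dataclasses.replace(
            config, nest_thetas=np.linspace(0.05, 0.95, config.n_nests))
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0x1F]).generate_state(1)[0])
    th = np.asarray(config.nest_thetas, dtype=float)
    w = np.exp(coupling * th)
    probs = w / w.sum()
    pinned = rng.choice(config.n_nests, size=config.n_immune_clusters, p=probs)
    return simulate_tissue(config, t_cluster_nests=pinned)


# ---------------------------------------------------------------------------
# neighborhood-structure fixture (for RCN recovery)
# ---------------------------------------------------------------------------

def simulate_neighborhood_fixture(seed: int = 0, zone_size: float = 400.0,
                                  density: float = 35000.0,
                                  gap: float = 200.0
                                  ) -> tuple[CellTable, pd.Series]:
    """Three well-separated zones with distinct neighborhood compositions:
    pure tumor, a 50/50 tumor + T cell interface, and stroma.  Returns the
    phenotyped cell table and the true zone label per cell.

    The default density is the saturated dense-compartment regime (the
    4-um hard core thins it to ~1.6e4 cells/mm^2, i.e. ~12 neighbors per
    15-um disc), where the 50/50 interface composition is resolvable against
    sampling noise at the standard neighborhood radius."""
    rng = np.random.default_rng(seed)
    zones = [("pure_tumor", lambda n: np.full(n, "tumor", dtype=object)),
             ("interface", lambda n: np.where(rng.uniform(size=n) < 0.5,
                                              "tumor", "T cell").astype(object)),
             ("stroma", lambda n: np.full(n, "stromal", dtype=object))]
    xs, ys, phenos, labels = [], [], [], []
    for zi, (zname, draw) in enumerate(zones):
        x0 = zi * (zone_size + gap)
        n = _poisson_count(rng, density, zone_size ** 2)
        pts = np.column_stack([rng.uniform(x0, x0 + zone_size, n),
                               rng.uniform(0, zone_size, n)])
        keep = _hardcore_thin(pts, 4.0, rng)
        pts = pts[keep]
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        phenos.append(draw(len(pts)))
        labels.append(np.full(len(pts), zname, dtype=object))
    data = pd.DataFrame({"cell_id": np.arange(sum(map(len, xs))),
                         "specimen_id": "FIX01",
                         "x": np.concatenate(xs), "y": np.concatenate(ys),
                         "dummy_marker": 1.0,
                         "phenotype": np.concatenate(phenos)})
    return (CellTable(data, ["dummy_marker"]),
            pd.Series(np.concatenate(labels), name="true_zone"))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: ExpressionSimConfig
                        ) -> tuple[ExpressionMatrix, dict]:
    """Simulate microregion x gene NB counts with a progression x inflammation
    latent structure.  Returns the matrix and the generative truth
    (per-MR factors, per-gene loadings and module labels)."""
    rng = np.random.default_rng(config.seed)
    n_mr, n_genes = config.n_microregions, config.n_genes
    prog = (np.asarray(config.progression, dtype=float)
            if config.progression is not None else rng.uniform(size=n_mr))
    infl = (np.asarray(config.inflammation, dtype=float)
            if config.inflammation is not None else rng.uniform(size=n_mr))

    n_mod = max(1, int(round(config.module_fraction * n_genes)))
    module = np.full(n_genes, "null", dtype=object)
    a = np.zeros(n_genes)
    b = np.zeros(n_genes)
    s = config.loading_scale
    module[:n_mod] = "progression_up";     a[:n_mod] = s
    module[n_mod:2 * n_mod] = "progression_down"; a[n_mod:2 * n_mod] = -s
    module[2 * n_mod:3 * n_mod] = "inflammation_up"; b[2 * n_mod:3 * n_mod] = s

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          n_genes)
    batch = np.repeat(np.arange(config.n_batches),
                      int(np.ceil(n_mr / config.n_batches)))[:n_mr]
    batch_offset = rng.normal(0.0, config.batch_sd, config.n_batches)

    log_mu = (baseline[None, :]
              + np.outer(prog - 0.5, a) + np.outer(infl - 0.5, b)
              + batch_offset[batch][:, None])
    mu = np.exp(log_mu)
    size = 1.0 / config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    mr_ids = [f"MR{i:03d}" for i in range(n_mr)]
    gene_ids = [f"G{j:04d}" for j in range(n_genes)]
    stage = np.array(["N", "P", "MIS", "RGP", "VGP"])[
        np.clip((prog * 5).astype(int), 0, 4)]
    meta = pd.DataFrame({
        "specimen": [f"SYN{1 + i % 6:02d}" for i in range(n_mr)],
        "stage": stage,
        "segment": "tumor",
        "batch": [f"set{b}" for b in batch],
    }, index=pd.Index(mr_ids, name="microregion_id"))
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=meta.index, columns=gene_ids), meta)
    truth = {
        "factors": pd.DataFrame({"progression": prog, "inflammation": infl},
                                index=meta.index),
        "loadings": pd.DataFrame({"a": a, "b": b, "module": module},
                                 index=gene_ids),
    }
    return matrix, truth
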