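"""Containers and readers/writers for the tabular and geometric formats the pipeline touches.

Three containers carry data between stages:

* :class:`CellTable` — one row per segmented cell: centroid coordinates (microns),
  per-marker mean fluorescence intensities, and the labels accumulated by later
  stages (rescaled intensities, phenotype, tumor state, region membership).
* :class:`RegionAnnotation` — a labelled polygon (or the epidermis reference
  polyline) in the same micron frame as the cells.
* :class:`ExpressionMatrix` — microregion x gene counts with per-microregion
  metadata (specimen, histologic stage, segment, batch).

Coordinates are stored internally in microns; pixel-space inputs are converted at
the boundary with a mandatory ``pixel_size``.
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix
from shapely.geometry import LineString, Polygon, mapping, shape

STAGES = ("N", "P", "MIS", "RGP", "VGP")
TIL_STATUSES = ("brisk", "non-brisk", "absent")
ROLES = ("histologic_region", "microregion", "epidermis_reference")

#: canonical CSV column names for cell tables (MCMICRO-style)
CELL_ID_COL = "CellID"
X_COL = "X_centroid"
Y_COL = "Y_centroid"
SPECIMEN_COL = "specimen_id"
RESERVED_COLS = {CELL_ID_COL, X_COL, Y_COL, SPECIMEN_COL,
                 "phenotype", "tumor_state", "region_id"}


class FormatError(ValueError):
    """Malformed input file (missing column, bad value, bad geometry)."""


@dataclasses.dataclass
class CellTable:
    """Per-cell records: the universal substrate of the pipeline.

    ``data`` has columns ``cell_id``, ``specimen_id``, ``x``, ``y`` (microns),
    one raw-intensity column per marker, and the optional label columns
    ``phenotype``, ``tumor_state``, ``region_id``.  Rescaled intensities, when
    present, live in ``rescaled`` (same index, one column per marker, in [0,1]).
    """

    data: pd.DataFrame
    markers: list[str]
    rescaled: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"cell_id", "specimen_id", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"cell table missing columns: {sorted(missing)}")
        for m in self.markers:
            if m not in self.data.columns:
                raise FormatError(f"marker column missing from cell table: {m!r}")
        if self.data.duplicated(subset=["specimen_id", "cell_id"]).any():
            raise FormatError("cell_id not unique within specimen_id")
        xy = self.data[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise FormatError("non-finite cell coordinates")
        raw = self.data[self.markers].to_numpy(float)
        if not np.isfinite(raw).all() or (raw < 0).any():
            raise FormatError("raw intensities must be finite and >= 0")
        if self.rescaled is not None:
            vals = self.rescaled.to_numpy(float)
            if ((vals < 0) | (vals > 1)).any():
                raise FormatError("rescaled intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def copy(self) -> "CellTable":
        return CellTable(self.data.copy(), list(self.markers),
                         None if self.rescaled is None else self.rescaled.copy())


@dataclasses.dataclass
class RegionAnnotation:
    """A labelled geometry in the cell tables' micron frame.

    ``stage`` is one of N/P/MIS/RGP/VGP (may be None only for the epidermis
    reference).  ``geometry`` is a simple polygon, or a polyline when
    ``role == "epidermis_reference"``.
    """

    region_id: str
    geometry: Polygon | LineString
    stage: str | None
    til_status: str | None = None
    role: str | None = "histologic_region"

    def __post_init__(self) -> None:
        if isinstance(self.geometry, LineString):
            if self.role != "epidermis_reference":
                raise FormatError(
                    f"region {self.region_id!r}: polyline geometry allowed only "
                    "for role 'epidermis_reference'")
        elif isinstance(self.geometry, Polygon):
            if not self.geometry.is_valid:
                raise FormatError(
                    f"region {self.region_id!r}: invalid (self-intersecting?) polygon")
        else:
            raise FormatError(
                f"region {self.region_id!r}: unsupported geometry "
                f"{self.geometry.geom_type}")
        if self.stage is None:
            if self.role != "epidermis_reference":
                raise FormatError(f"region {self.region_id!r}: stage required")
        elif self.stage not in STAGES:
            raise FormatError(
                f"region {self.region_id!r}: unknown stage {self.stage!r}; "
                f"expected one of {STAGES}")
        if self.til_status is not None and self.til_status not in TIL_STATUSES:
            raise FormatError(
                f"region {self.region_id!r}: unknown til_status {self.til_status!r}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive point-in-polygon membership for centroids."""
        pts = shapely.points(np.column_stack([x, y]))
        return shapely.covers(self.geometry, pts)


@dataclasses.dataclass
class ExpressionMatrix:
    """Microregion x gene counts with per-microregion metadata.

    ``values``: DataFrame indexed by microregion id, columns = gene ids.
    ``mr_metadata``: DataFrame indexed by microregion id with at least
    ``specimen`` and ``stage``; ``segment`` and ``batch`` are optional.
    """

    values: pd.DataFrame
    mr_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mr_metadata.index):
            raise FormatError("expression values and metadata indices differ")
        for col in ("specimen", "stage"):
            if col not in self.mr_metadata.columns:
                raise FormatError(f"microregion metadata missing column {col!r}")
            if self.mr_metadata[col].isna().any():
                bad = self.mr_metadata.index[self.mr_metadata[col].isna()].tolist()
                raise FormatError(f"missing {col!r} for microregions {bad}")
        if (self.values.to_numpy(float) < 0).any():
            raise FormatError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def microregion_ids(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path, pixel_size: float,
                    units: str = "pixels") -> CellTable:
    """Read an MCMICRO-style single-cell CSV.

    Parameters
    ----------
    path:
        CSV with columns ``CellID``, ``X_centroid``, ``Y_centroid``, optionally
        ``specimen_id``, and one column per marker.
    pixel_size:
        Microns per pixel; coordinates are multiplied by it when
        ``units == "pixels"``.
    units:
        ``"pixels"`` (default) or ``"microns"`` — the unit the CSV's
        coordinates are declared in.
    """
    path = Path(path)
    if units not in ("pixels", "microns"):
        raise ValueError(f"units must be 'pixels' or 'microns', got {units!r}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty cell table") from None
    for col in (CELL_ID_COL, X_COL, Y_COL):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    markers = [c for c in df.columns if c not in RESERVED_COLS]
    if not markers:
        raise FormatError(f"{path}: no marker columns found")
    for m in markers:
        numeric = pd.to_numeric(df[m], errors="coerce")
        bad = numeric.isna() & df[m].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric intensity in column {m!r} at row {row}")
        df[m] = numeric
    scale = pixel_size if units == "pixels" else 1.0
    out = pd.DataFrame({
        "cell_id": df[CELL_ID_COL].to_numpy(),
        "specimen_id": df[SPECIMEN_COL] if SPECIMEN_COL in df.columns else path.stem,
        "x": df[X_COL].to_numpy(float) * scale,
        "y": df[Y_COL].to_numpy(float) * scale,
    })
    for m in markers:
        out[m] = df[m].to_numpy(float)
    for extra in ("phenotype", "tumor_state", "region_id"):
        if extra in df.columns:
            out[extra] = df[extra]
    return CellTable(out, markers)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table back to the MCMICRO-style CSV (coordinates in microns)."""
    df = table.data
    out = pd.DataFrame({CELL_ID_COL: df["cell_id"],
                        SPECIMEN_COL: df["specimen_id"],
                        X_COL: df["x"], Y_COL: df["y"]})
    for m in table.markers:
        out[m] = df[m]
    for extra in ("phenotype", "tumor_state", "region_id"):
        if extra in df.columns:
            out[extra] = df[extra]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# region annotations (GeoJSON)
# ---------------------------------------------------------------------------

def read_region_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read a GeoJSON FeatureCollection of region annotations (micron frame)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        regions.append(RegionAnnotation(
            region_id=str(props.get("region_id", f"region_{i}")),
            geometry=geom,
            stage=props.get("stage"),
            til_status=props.get("til_status"),
            role=props.get("role", "histologic_region"),
        ))
    return regions


def write_region_annotations(regions: Sequence[RegionAnnotation],
                             path: str | Path) -> None:
    features = []
    for r in regions:
        features.append({
            "type": "Feature",
            "geometry": mapping(r.geometry),
            "properties": {"region_id": r.region_id, "stage": r.stage,
                           "til_status": r.til_status, "role": r.role},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(counts_path: str | Path,
                           metadata_path: str | Path) -> ExpressionMatrix:
    """Read microregion x gene counts (CSV, or MTX with sidecar index files)
    and join per-microregion metadata (TSV keyed by microregion id)."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        mat = mmread(counts_path).toarray()
        rows = _read_index(counts_path.with_suffix(".rows.txt"))
        cols = _read_index(counts_path.with_suffix(".cols.txt"))
        values = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        values = pd.read_csv(counts_path, index_col=0)
        values.index = values.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    unmatched = values.index.difference(meta.index)
    if len(unmatched):
        raise FormatError(
            f"microregions without metadata: {sorted(unmatched.tolist())}")
    meta = meta.loc[values.index]
    return ExpressionMatrix(values, meta)


def write_expression_matrix(matrix: ExpressionMatrix, counts_path: str | Path,
                            metadata_path: str | Path) -> None:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        buf = io.BytesIO()
        mmwrite(buf, coo_matrix(matrix.values.to_numpy()))
        counts_path.write_bytes(buf.getvalue())
        _write_index(counts_path.with_suffix(".rows.txt"), matrix.microregion_ids)
        _write_index(counts_path.with_suffix(".cols.txt"), matrix.gene_ids)
    else:
        matrix.values.to_csv(counts_path)
    matrix.mr_metadata.to_csv(metadata_path, sep="\t")


def _read_index(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"MTX sidecar index missing: {path}")
    return path.read_text().splitlines()


def _write_index(path: Path, names: Sequence[str]) -> None:
    path.write_text("\n".join(str(n) for n in names) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "pixel_size": 0.325,        # microns per pixel (20x CyCIF)
    "neighborhood_radius": 15.0,  # microns, radius-based neighborhoods
    "rcn_k": 25,
    "rcng_g": 11,
    "band_width": 200.0,        # microns (0.2 mm invasion bands)
    "som_grid": [30, 30],
    "som_threshold": 0.95,
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load the run configuration (YAML), filling unset keys with defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a mapping")
        config.update(user)
    return config
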