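"""End-to-end pipeline with provenance manifest.

Stages run in order (simulate -> phenotype -> entropy -> rcn -> bands ->
proximity -> som); every stage records SHA-256 hashes of its input and output
files in a run manifest, so reruns skip stages whose inputs are unchanged and
corrupted intermediates are detected by hash mismatch.  A single global seed
is expanded into independent per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import (bands_proximity, core_io, entropy, neighborhoods, phenotyping,
               som_trajectory, synthetic_tissue)

STAGE_ORDER = ("simulate", "phenotype", "entropy", "rcn", "bands",
               "proximity", "som")


class StageError(RuntimeError):
    pass


class HashMismatchError(RuntimeError):
    pass


@dataclasses.dataclass
class RunManifest:
    """Config snapshot, per-stage seeds, and input/output file hashes."""

    config: dict
    seeds: dict
    version: str
    stages: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, inputs: dict, outputs: dict) -> None:
        self.stages[stage] = {"inputs": inputs, "outputs": outputs,
                              "timestamp": time.time()}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_files(paths: dict[str, Path]) -> dict[str, str]:
    return {name: _sha256(p) for name, p in paths.items()}


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGE_ORDER))
    return {stage: int(c.generate_state(1)[0] % (2 ** 31))
            for stage, c in zip(STAGE_ORDER, children)}


def run_pipeline(config: dict, outdir, resume: bool = True) -> RunManifest:
    """Run the synthetic end-to-end pipeline into ``outdir``.

    ``config`` follows :data:`melspat.core_io.DEFAULT_CONFIG`, plus optional
    ``tissue`` and ``expression`` sub-dicts forwarded to the simulator
    configs.  With ``resume=True`` a stage is skipped when the manifest shows
    identical input hashes and its recorded outputs still hash-match
    (a corrupted intermediate raises :class:`HashMismatchError`).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {**core_io.DEFAULT_CONFIG, **config}
    seeds = _stage_seeds(int(config["seed"]))
    manifest_path = outdir / "manifest.json"
    previous = (RunManifest.load(manifest_path)
                if resume and manifest_path.exists() else None)
    manifest = RunManifest(config=config, seeds=seeds, version=_version())

    paths = {
        "cells": outdir / "cells.csv",
        "regions": outdir / "regions.geojson",
        "truth": outdir / "truth.tsv",
        "gates": outdir / "gates.tsv",
        "counts": outdir / "counts.csv",
        "mr_meta": outdir / "mr_meta.tsv",
        "cells_phenotyped": outdir / "cells_phenotyped.csv",
        "region_entropy": outdir / "region_entropy.tsv",
        "rcn_labels": outdir / "rcn_labels.tsv",
        "rcn_centroids": outdir / "rcn_centroids.tsv",
        "band_entropy": outdir / "band_entropy.tsv",
        "proximity": outdir / "proximity.tsv",
        "som_tree": outdir / "som_tree.tsv",
        "som_branches": outdir / "som_branches.tsv",
        "som_clusters": outdir / "som_clusters.tsv",
    }

    stage_io = {
        "simulate": ([], ["cells", "regions", "truth", "gates", "counts",
                          "mr_meta"]),
        "phenotype": (["cells", "gates"], ["cells_phenotyped"]),
        "entropy": (["cells_phenotyped", "regions"], ["region_entropy"]),
        "rcn": (["cells_phenotyped"], ["rcn_labels", "rcn_centroids"]),
        "bands": (["cells_phenotyped", "regions"], ["band_entropy"]),
        "proximity": (["cells_phenotyped", "regions"], ["proximity"]),
        "som": (["counts", "mr_meta"], ["som_tree", "som_branches",
                                        "som_clusters"]),
    }
    runners = {
        "simulate": _stage_simulate, "phenotype": _stage_phenotype,
        "entropy": _stage_entropy, "rcn": _stage_rcn, "bands": _stage_bands,
        "proximity": _stage_proximity, "som": _stage_som,
    }

    for stage in STAGE_ORDER:
        in_names, out_names = stage_io[stage]
        in_paths = {n: paths[n] for n in in_names}
        out_paths = {n: paths[n] for n in out_names}
        in_hashes = _hash_files(in_paths)
        if previous is not None and _can_skip(previous, stage, in_hashes,
                                              out_paths):
            manifest.stages[stage] = previous.stages[stage]
            continue
        try:
            runners[stage](config, seeds[stage], paths)
        except Exception as exc:
            manifest.record(stage, in_hashes, {"error": str(exc)})
            manifest.save(manifest_path)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, in_hashes, _hash_files(out_paths))
        manifest.save(manifest_path)
    manifest.save(manifest_path)
    return manifest


def _can_skip(previous: RunManifest, stage: str, in_hashes: dict,
              out_paths: dict[str, Path]) -> bool:
    rec = previous.stages.get(stage)
    if rec is None or rec["inputs"] != in_hashes or "error" in rec["outputs"]:
        return False
    for name, path in out_paths.items():
        if not path.exists():
            return False
        if _sha256(path) != rec["outputs"].get(name):
            raise HashMismatchError(
                f"intermediate file {path} does not match the manifest hash "
                f"recorded for stage {stage!r}")
    return True


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("melspat")
    except PackageNotFoundError:
        return "unknown"


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _tissue_config(config: dict, seed: int) -> synthetic_tissue.TissueSimConfig:
    kwargs = dict(config.get("tissue", {}))
    kwargs.setdefault("seed", seed)
    return synthetic_tissue.TissueSimConfig(**kwargs)


def _stage_simulate(config: dict, seed: int, paths: dict) -> None:
    tcfg = _tissue_config(config, seed)
    cells, regions, truth = synthetic_tissue.simulate_tissue(tcfg)
    core_io.write_cell_table(cells, paths["cells"])
    core_io.write_region_annotations(regions, paths["regions"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    synthetic_tissue.true_gates(tcfg).to_tsv(paths["gates"])
    ecfg_kwargs = dict(config.get("expression", {}))
    ecfg_kwargs.setdefault("seed", seed + 1)
    matrix, _ = synthetic_tissue.simulate_expression(
        synthetic_tissue.ExpressionSimConfig(**ecfg_kwargs))
    core_io.write_expression_matrix(matrix, paths["counts"], paths["mr_meta"])


def _stage_phenotype(config: dict, seed: int, paths: dict) -> None:
    cells = core_io.read_cell_table(paths["cells"], pixel_size=1.0,
                                    units="microns")
    gates = phenotyping.GateSet.from_tsv(paths["gates"])
    cells = phenotyping.rescale_table(cells, gates)
    cells = phenotyping.call_phenotypes(cells)
    cells = phenotyping.assign_tumor_states(cells)
    core_io.write_cell_table(cells, paths["cells_phenotyped"])


def _load_phenotyped(paths: dict) -> core_io.CellTable:
    return core_io.read_cell_table(paths["cells_phenotyped"], pixel_size=1.0,
                                   units="microns")


def _stage_entropy(config: dict, seed: int, paths: dict) -> None:
    cells = _load_phenotyped(paths)
    regions = core_io.read_region_annotations(paths["regions"])
    results = entropy.entropy_by_region(cells, regions, "tumor_state")
    entropy.entropy_table(results).to_csv(paths["region_entropy"], sep="\t",
                                          index=False)


def _stage_rcn(config: dict, seed: int, paths: dict) -> None:
    cells = _load_phenotyped(paths)
    matrix = neighborhoods.neighborhood_composition(
        cells, r=config["neighborhood_radius"])
    k = min(config["rcn_k"],
            len(np.unique(matrix.frequencies.loc[~matrix.isolated].to_numpy(),
                          axis=0)))
    model = neighborhoods.cluster_rcn(matrix, k=k, seed=seed)
    model = neighborhoods.group_rcns(model, g=min(config["rcng_g"], k))
    out = pd.DataFrame({"cell_id": cells.data["cell_id"],
                        "rcn": model.labels.to_numpy(),
                        "rcng": model.rcng_labels().to_numpy()})
    out.to_csv(paths["rcn_labels"], sep="\t", index=False)
    model.centroids.to_csv(paths["rcn_centroids"], sep="\t")


def _stage_bands(config: dict, seed: int, paths: dict) -> None:
    cells = _load_phenotyped(paths)
    regions = core_io.read_region_annotations(paths["regions"])
    reference = next((r for r in regions if r.role == "epidermis_reference"),
                     None)
    distances = bands_proximity.distance_to_epidermis(cells, reference)
    bands = bands_proximity.assign_bands(distances, config["band_width"])
    results = bands_proximity.entropy_by_band(cells, bands, regions,
                                              "tumor_state")
    entropy.entropy_table(results).to_csv(paths["band_entropy"], sep="\t",
                                          index=False)


def _stage_proximity(config: dict, seed: int, paths: dict) -> None:
    cells = _load_phenotyped(paths)
    profile = bands_proximity.proximity_profile(
        cells, "melanocytic", "NC-like", r=config["neighborhood_radius"],
        group_col="specimen_id")
    (profile.comparisons if profile.status == "ok"
     else pd.DataFrame([{"status": profile.status}])
     ).to_csv(paths["proximity"], sep="\t", index=False)


def _stage_som(config: dict, seed: int, paths: dict) -> None:
    matrix = core_io.read_expression_matrix(paths["counts"], paths["mr_meta"])
    normalized = som_trajectory.preprocess_expression(matrix)
    model = som_trajectory.train_som(normalized,
                                     grid=tuple(config["som_grid"]), seed=seed)
    areas = som_trajectory.overexpression_clusters(
        model, threshold=config["som_threshold"])
    tree = som_trajectory.correlation_spanning_tree(
        som_trajectory.metagene_profiles(model))
    branches = som_trajectory.decompose_branches(tree)
    tree.to_edge_table().to_csv(paths["som_tree"], sep="\t", index=False)
    pd.DataFrame(sorted(branches.items()),
                 columns=["microregion_id", "branch"]
                 ).to_csv(paths["som_branches"], sep="\t", index=False)
    areas.clusters.to_csv(paths["som_clusters"], sep="\t", index=False)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(outdir, with_figures: bool = True) -> Path:
    """Summarize a completed run: per-region H, RCNG proportions, branches."""
    outdir = Path(outdir)
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    region_h = pd.read_csv(outdir / "region_entropy.tsv", sep="\t")
    rcn = pd.read_csv(outdir / "rcn_labels.tsv", sep="\t")
    branches = pd.read_csv(outdir / "som_branches.tsv", sep="\t")
    rcng_prop = (rcn[rcn["rcng"] >= 0]["rcng"].value_counts(normalize=True)
                 .sort_index().rename("proportion"))
    summary = report_dir / "summary.tsv"
    with open(summary, "w") as fh:
        fh.write("# per-region spatial entropy\n")
        region_h.to_csv(fh, sep="\t", index=False)
        fh.write("\n# global RCNG proportions\n")
        rcng_prop.to_csv(fh, sep="\t")
        fh.write("\n# CST branch sizes\n")
        branches["branch"].value_counts().to_csv(fh, sep="\t")
    if with_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        ok = region_h[region_h["status"] == "ok"]
        axes[0].bar(ok["region_id"], ok["H"])
        axes[0].set_ylabel("spatial entropy H (bits/um)")
        axes[0].tick_params(axis="x", rotation=90)
        rcng_prop.plot.bar(ax=axes[1])
        axes[1].set_ylabel("RCNG proportion")
        fig.tight_layout()
        fig.savefig(report_dir / "summary.png", dpi=120)
        plt.close(fig)
    return summary
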