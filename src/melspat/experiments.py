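"""Reference synthetic experiments exercising the pipeline end to end.

These functions wire the generators to the analysis stages under fixed study
designs, so that the same experiment definitions back both the test suite and
result reproduction:

* :func:`theta_entropy_curve` — does region-level spatial entropy rise
  monotonically with the planted intermixing parameter theta?
* :func:`immune_coupling_pvalue` — with immune infiltrates preferentially
  seeded near high-intermixing nests, do high-entropy regions carry a higher
  T-cell proportion than low-entropy ones (rank-sum test), and is the test
  silent when the coupling is absent?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .entropy import compare_groups, entropy_by_region
from .phenotyping import assign_tumor_states, call_phenotypes, rescale_table
from .synthetic_tissue import (TissueSimConfig, simulate_coupled_infiltrate,
                               simulate_tissue, true_gates)


def theta_entropy_curve(thetas=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                        n_seeds: int = 20, seed0: int = 0,
                        **config_kwargs) -> pd.DataFrame:
    """Mean region-level H per theta over independent tissue simulations.

    Tumor states come from the generator's ground truth, so the curve
    isolates the entropy statistic's response to planted intermixing.
    Returns one row per (theta, seed) with the mean H over computable
    regions.
    """
    rows = []
    for theta in thetas:
        for s in range(n_seeds):
            cfg = TissueSimConfig(seed=seed0 + s, theta=theta, **config_kwargs)
            cells, regions, truth = simulate_tissue(cfg)
            cells.data["tumor_state"] = truth["true_state"].to_numpy()
            res = entropy_by_region(cells, regions, "tumor_state")
            hs = [r.H for r in res if r.status == "ok"]
            rows.append({"theta": theta, "seed": seed0 + s,
                         "mean_H": float(np.mean(hs)) if hs else np.nan})
    return pd.DataFrame(rows)


def immune_coupling_pvalue(seed: int, coupling: float, n_nests: int = 16,
                           phenotype_from_markers: bool = True) -> float:
    """One run of the immune-entropy association experiment.

    A tissue is simulated with bimodal nest intermixing (theta 0.1 / 0.9) and
    immune clusters pinned to nests with softmax weight exp(coupling * theta).
    Cells are phenotyped from marker intensities via the true gates (or taken
    from ground truth when ``phenotype_from_markers`` is False), per-nest
    spatial entropy is computed on tumor states, every non-tumor cell is
    assigned to its nearest nest, and the per-nest T-cell proportions of the
    upper and lower entropy halves are compared with a two-sided rank-sum
    test.  Returns the p-value (NaN if fewer than 3 nests per half were
    computable).
    """
    thetas = np.tile([0.1, 0.9], n_nests // 2)
    cfg = TissueSimConfig(seed=seed, n_nests=n_nests, n_immune_clusters=22,
                          immune_cluster_size=50.0,
                          field_size=(2600.0, 1700.0), nest_thetas=thetas)
    cells, regions, truth = simulate_coupled_infiltrate(cfg, coupling)
    if phenotype_from_markers:
        cells = rescale_table(cells, true_gates(cfg))
        cells = call_phenotypes(cells)
        cells = assign_tumor_states(cells)
    else:
        cells.data["phenotype"] = truth["true_phenotype"].to_numpy()
        cells.data["tumor_state"] = truth["true_state"].to_numpy()

    results = {r.region_id: r
               for r in entropy_by_region(cells, regions, "tumor_state")}
    polys = [r for r in regions if r.role != "epidermis_reference"]
    centers = np.array([[r.geometry.centroid.x, r.geometry.centroid.y]
                        for r in polys])
    pheno = cells.data["phenotype"].to_numpy()
    nontumor = pheno != "tumor"
    pts = cells.data[["x", "y"]].to_numpy()[nontumor]
    t_flag = pheno[nontumor] == "T cell"
    _, nearest = cKDTree(centers).query(pts)

    Hs, props = [], []
    for k, r in enumerate(polys):
        er = results.get(r.region_id)
        if er is None or er.status != "ok":
            continue
        mask = nearest == k
        if not mask.any():
            continue
        Hs.append(er.H)
        props.append(float(t_flag[mask].mean()))
    Hs, props = np.array(Hs), np.array(props)
    med = np.median(Hs)
    hi, lo = props[Hs > med], props[Hs <= med]
    if min(len(hi), len(lo)) < 3:
        return float("nan")
    return compare_groups(hi, lo, test="rank_sum").pvalue


def immune_coupling_rejection_rate(coupling: float, n_seeds: int = 40,
                                   seed0: int = 0, alpha: float = 0.05,
                                   **kwargs) -> float:
    """Fraction of seeds where the coupling experiment rejects at ``alpha``."""
    ps = np.array([immune_coupling_pvalue(seed0 + s, coupling, **kwargs)
                   for s in range(n_seeds)])
    ps = ps[~np.isnan(ps)]
    return float((ps < alpha).mean())
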