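"""Generative-model contracts: determinism, planted structure, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score

from melspat.synthetic_tissue import (CapacityError, ExpressionSimConfig,
                                      TissueSimConfig, _poisson_count,
                                      simulate_coupled_infiltrate,
                                      simulate_expression,
                                      simulate_neighborhood_fixture,
                                      simulate_tissue)


class TestTissueSimulation:
    def test_same_seed_identical_output(self):
        cfg = TissueSimConfig(seed=5)
        cells1, _, truth1 = simulate_tissue(cfg)
        cells2, _, truth2 = simulate_tissue(TissueSimConfig(seed=5))
        pd.testing.assert_frame_equal(cells1.data, cells2.data)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seed_differs(self):
        cells1, _, _ = simulate_tissue(TissueSimConfig(seed=5))
        cells2, _, _ = simulate_tissue(TissueSimConfig(seed=6))
        assert len(cells1) != len(cells2) or \
            not np.allclose(cells1.coords[:10], cells2.coords[:10])

    def test_theta_zero_nests_are_single_state(self):
        _, _, truth = simulate_tissue(TissueSimConfig(seed=7, theta=0.0))
        for nest, grp in truth[truth["nest_id"] >= 0].groupby("nest_id"):
            assert grp["true_state"].nunique() == 1

    def test_hard_core_spacing_respected(self):
        cells, _, _ = simulate_tissue(TissueSimConfig(seed=8))
        from scipy.spatial import cKDTree
        tree = cKDTree(cells.coords)
        pairs = tree.query_pairs(4.0 - 1e-9)
        assert len(pairs) == 0

    def test_state_mixture_matches_theta_expectation(self):
        """theta=0.8, 4 states: P(cell keeps the dominant state) =
        (1-theta) + theta/4 = 0.4; pooled over seeds the observed dominant
        frequency must sit within 3 sigma of the binomial expectation."""
        theta, n_states = 0.8, 4
        p_dom = (1 - theta) + theta / n_states
        kept = total = 0
        for seed in range(20):
            _, _, truth = simulate_tissue(TissueSimConfig(seed=seed,
                                                          theta=theta))
            tumor = truth[truth["nest_id"] >= 0]
            for nest, grp in tumor.groupby("nest_id"):
                dominant = grp["true_state"].mode().iloc[0]
                kept += (grp["true_state"] == dominant).sum()
                total += len(grp)
        se = np.sqrt(p_dom * (1 - p_dom) / total)
        # mode-based dominant estimate biases the pooled frequency upward by
        # O(1/n_nest); allow the binomial band plus that small-sample slack
        assert abs(kept / total - p_dom) < 3 * se + 0.01

    def test_compartment_counts_are_poisson(self):
        """Dispersion index of the pre-thinning Poisson draw over 100 seeds."""
        counts = [_poisson_count(np.random.default_rng(s), 1200.0, 5e5)
                  for s in range(100)]
        counts = np.array(counts, dtype=float)
        d = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], len(counts) - 1)
        assert lo < d < hi

    def test_capacity_error(self):
        cfg = TissueSimConfig(field_size=(1e5, 1e5))
        with pytest.raises(CapacityError):
            simulate_tissue(cfg)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_theta_range_validated(self, bad):
        with pytest.raises(ValueError, match="theta"):
            TissueSimConfig(theta=bad)

    def test_heterotypic_edge_fraction_nondecreasing_in_theta(self):
        """theta monotonically controls planted intermixing (averaged over
        seeds, checked on the Delaunay graph within nests)."""
        from melspat.spatial_graph import build_delaunay_graph
        fracs = []
        for theta in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = []
            for seed in range(5):
                cells, _, truth = simulate_tissue(
                    TissueSimConfig(seed=seed, theta=theta))
                cells.data["tumor_state"] = truth["true_state"].to_numpy()
                for nest, grp in truth[truth["nest_id"] >= 0].groupby("nest_id"):
                    if len(grp) < 10:
                        continue
                    g = build_delaunay_graph(cells.data.loc[grp.index],
                                             "tumor_state")
                    a, b = g.edges[:, 0], g.edges[:, 1]
                    vals.append((g.attributes[a] != g.attributes[b]).mean())
            fracs.append(np.mean(vals))
        assert all(np.diff(fracs) >= -1e-9), fracs


class TestCoupledInfiltrate:
    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            simulate_coupled_infiltrate(TissueSimConfig(), -1.0)

    def test_zero_coupling_independent_of_theta(self):
        """Correlation between nest theta and nearby T-cell density ~ 0."""
        from scipy.spatial import cKDTree
        corrs = []
        for seed in range(30):
            thetas = np.linspace(0.05, 0.95, 8)
            cfg = TissueSimConfig(seed=seed, n_nests=8, nest_thetas=thetas,
                                  field_size=(2000.0, 1400.0))
            cells, regions, truth = simulate_coupled_infiltrate(cfg, 0.0)
            polys = [r for r in regions if r.role != "epidermis_reference"]
            centers = np.array([[r.geometry.centroid.x, r.geometry.centroid.y]
                                for r in polys])
            t_pts = cells.coords[(truth["true_phenotype"] == "T cell")
                                 .to_numpy()]
            _, nearest = cKDTree(centers).query(t_pts)
            dens = np.bincount(nearest, minlength=len(polys))
            corrs.append(stats.spearmanr(thetas, dens).statistic)
        mean_corr = np.nanmean(corrs)
        assert abs(mean_corr) < 3 * np.nanstd(corrs) / np.sqrt(len(corrs)) + 0.1

    def test_positive_coupling_concentrates_t_cells(self):
        from scipy.spatial import cKDTree
        corrs = []
        for seed in range(10):
            thetas = np.linspace(0.05, 0.95, 8)
            cfg = TissueSimConfig(seed=seed, n_nests=8, nest_thetas=thetas,
                                  field_size=(2000.0, 1400.0))
            cells, regions, truth = simulate_coupled_infiltrate(cfg, 8.0)
            polys = [r for r in regions if r.role != "epidermis_reference"]
            centers = np.array([[r.geometry.centroid.x, r.geometry.centroid.y]
                                for r in polys])
            t_pts = cells.coords[(truth["true_phenotype"] == "T cell")
                                 .to_numpy()]
            _, nearest = cKDTree(centers).query(t_pts)
            dens = np.bincount(nearest, minlength=len(polys))
            corrs.append(stats.spearmanr(thetas, dens).statistic)
        assert np.mean(corrs) > 0.5


class TestNeighborhoodFixture:
    def test_zones_have_planted_compositions(self):
        cells, zones = simulate_neighborhood_fixture(seed=1)
        df = cells.data
        assert (df.loc[zones == "pure_tumor", "phenotype"] == "tumor").all()
        assert (df.loc[zones == "stroma", "phenotype"] == "stromal").all()
        interface = df.loc[zones == "interface", "phenotype"]
        assert 0.4 < (interface == "T cell").mean() < 0.6


class TestExpressionSimulation:
    def test_deterministic(self):
        m1, t1 = simulate_expression(ExpressionSimConfig(seed=4))
        m2, t2 = simulate_expression(ExpressionSimConfig(seed=4))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1["factors"], t2["factors"])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            ExpressionSimConfig(n_genes=5)

    def test_identical_factors_near_duplicate_profiles(self):
        """Two microregions with the same latent factors and vanishing
        overdispersion have correlation -> 1 (log scale)."""
        n = 10
        cfg = ExpressionSimConfig(
            seed=2, n_microregions=n, n_genes=400,
            progression=[0.5] * 2 + list(np.linspace(0, 1, n - 2)),
            inflammation=[0.5] * 2 + list(np.linspace(1, 0, n - 2)),
            baseline_log_mean=6.0, dispersion=1e-3)
        matrix, _ = simulate_expression(cfg)
        a, b = np.log1p(matrix.values.iloc[0]), np.log1p(matrix.values.iloc[1])
        assert np.corrcoef(a, b)[0, 1] > 0.98

    def test_zero_loadings_make_microregions_exchangeable(self):
        cfg = ExpressionSimConfig(seed=3, loading_scale=0.0, n_genes=200)
        matrix, truth = simulate_expression(cfg)
        assert (truth["loadings"][["a", "b"]] == 0).all().all()
        # group means of random halves differ only by sampling noise
        X = np.log1p(matrix.values.to_numpy())
        half = len(X) // 2
        diff = np.abs(X[:half].mean(0) - X[half:].mean(0))
        pooled_se = np.sqrt(X.var(0) * (1 / half + 1 / (len(X) - half)))
        assert (diff < 5 * pooled_se + 1e-3).mean() > 0.99

    def test_planted_modules_recovered_by_correlation_clustering(self):
        cfg = ExpressionSimConfig(seed=6, n_microregions=80, n_genes=300)
        matrix, truth = simulate_expression(cfg)
        loaded = truth["loadings"]["module"] != "null"
        X = np.log1p(matrix.values.to_numpy()).T[loaded.to_numpy()]
        corr_dist = 1 - np.corrcoef(X)
        labels = AgglomerativeClustering(
            n_clusters=3, metric="precomputed", linkage="average"
        ).fit_predict(corr_dist)
        ari = adjusted_rand_score(
            truth["loadings"].loc[loaded, "module"], labels)
        assert ari >= 0.9

    def test_batch_offsets_shift_means(self):
        cfg = ExpressionSimConfig(seed=9, n_batches=2, batch_sd=1.0,
                                  loading_scale=0.0)
        matrix, _ = simulate_expression(cfg)
        g = np.log1p(matrix.values).groupby(
            matrix.mr_metadata["batch"]).mean()
        assert abs(g.iloc[0].mean() - g.iloc[1].mean()) > 0.05
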