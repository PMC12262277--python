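"""Expression preprocessing, SOM training, portraits, cluster areas, CST."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from melspat.core_io import ExpressionMatrix
from melspat.som_trajectory import (correlation_spanning_tree,
                                    decompose_branches, difference_portrait,
                                    group_portrait, metagene_profiles,
                                    overexpression_clusters,
                                    preprocess_expression, sample_portrait,
                                    train_som)
from melspat.synthetic_tissue import ExpressionSimConfig, simulate_expression


def _matrix(seed=0, n_mr=20, n_genes=200, **kw):
    cfg = ExpressionSimConfig(seed=seed, n_microregions=n_mr,
                              n_genes=n_genes, **kw)
    return simulate_expression(cfg)[0]


@pytest.fixture(scope="module")
def trained():
    matrix = _matrix(seed=1, n_mr=24, n_genes=300)
    normalized = preprocess_expression(matrix)
    return normalized, train_som(normalized, grid=(8, 8), seed=0)


class TestPreprocess:
    def test_identical_samples_stay_identical(self):
        matrix = _matrix(seed=2, n_mr=10)
        vals = matrix.values.copy()
        vals.iloc[1] = vals.iloc[0]
        matrix = ExpressionMatrix(vals, matrix.mr_metadata)
        norm = preprocess_expression(matrix)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_gene_means_centered(self):
        norm = preprocess_expression(_matrix(seed=3))
        assert np.allclose(norm.mean(axis=1), 0.0, atol=1e-12)

    def test_quantile_normalization_equalizes_distributions(self):
        """On tie-free data every sample ends with the same sorted values
        (with ties, tie-averaging perturbs only the tied entries)."""
        from melspat.som_trajectory import _quantile_normalize
        X = np.random.default_rng(4).normal(size=(200, 8))  # ties a.s. absent
        Q = _quantile_normalize(X)
        ref = np.sort(Q[:, 0])
        for j in range(1, Q.shape[1]):
            assert np.allclose(np.sort(Q[:, j]), ref, atol=1e-12)

    def test_quantile_normalization_preserves_within_sample_order(self):
        matrix = _matrix(seed=4)
        X = np.log10(matrix.values.to_numpy(float).T + 1.0)
        from melspat.som_trajectory import _quantile_normalize
        Q = _quantile_normalize(X)
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            assert (np.diff(Q[order, j]) >= -1e-12).all()


class TestTrainSOM:
    def test_30x30_grid_yields_900_metagenes(self):
        matrix = _matrix(seed=5, n_mr=20, n_genes=400)
        model = train_som(preprocess_expression(matrix), grid=(30, 30),
                          seed=0)
        assert model.n_metagenes == 900
        assert model.codebook.shape == (900, 20)

    def test_quantization_error_decreases(self, trained):
        _, model = trained
        qe = model.quantization_errors
        assert qe[-1] <= qe[0]

    def test_deterministic(self):
        matrix = _matrix(seed=6, n_mr=16, n_genes=200)
        norm = preprocess_expression(matrix)
        m1 = train_som(norm, grid=(6, 6), seed=3)
        m2 = train_som(norm, grid=(6, 6), seed=3)
        assert np.allclose(m1.codebook, m2.codebook, atol=1e-12)
        assert (m1.bmu == m2.bmu).all()

    def test_every_gene_has_one_bmu(self, trained):
        norm, model = trained
        assert len(model.bmu) == len(norm)
        assert ((model.bmu >= 0) & (model.bmu < model.n_units)).all()

    def test_anticorrelated_modules_map_to_disjoint_patches(self):
        """Two planted opposing gene modules end on separate, internally
        connected regions of the map."""
        rng = np.random.default_rng(7)
        n_samples = 20
        t = np.linspace(-1, 1, n_samples)
        up = t[None, :] + rng.normal(0, 0.15, (40, n_samples))
        down = -t[None, :] + rng.normal(0, 0.15, (40, n_samples))
        X = pd.DataFrame(np.vstack([up, down]),
                         index=[f"g{i}" for i in range(80)],
                         columns=[f"s{j}" for j in range(n_samples)])
        model = train_som(X, grid=(8, 8), seed=0)
        units_up = set(model.bmu[:40])
        units_down = set(model.bmu[40:])
        assert units_up.isdisjoint(units_down)
        for units in (units_up, units_down):
            sub = nx.Graph()
            sub.add_nodes_from(units)
            for u, v in itertools.combinations(units, 2):
                du = divmod(u, 8)
                dv = divmod(v, 8)
                if abs(du[0] - dv[0]) + abs(du[1] - dv[1]) == 1:
                    sub.add_edge(u, v)
            assert nx.number_connected_components(sub) == 1

    def test_per_batch_fit_isolates_batches(self):
        matrix = _matrix(seed=15, n_mr=24, n_genes=150, n_batches=2)
        from melspat.som_trajectory import train_som_per_batch
        models = train_som_per_batch(matrix, grid=(5, 5), seed=0)
        assert set(models) == {"set0", "set1"}
        sizes = matrix.mr_metadata["batch"].value_counts()
        for batch, model in models.items():
            assert model.codebook.shape == (25, sizes[batch])

    def test_single_sample_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 1)))
        with pytest.raises(ValueError, match="2 samples"):
            train_som(X, grid=(4, 4), seed=0)


class TestPortraits:
    def test_group_of_one_equals_sample_portrait(self, trained):
        _, model = trained
        s = model.sample_ids[0]
        assert np.array_equal(group_portrait(model, [s]),
                              sample_portrait(model, s))

    def test_difference_of_identical_is_zero(self, trained):
        _, model = trained
        p = sample_portrait(model, model.sample_ids[0])
        assert np.all(difference_portrait(p, p) == 0.0)

    def test_partition_means_recombine_linearly(self, trained):
        _, model = trained
        ids = model.sample_ids
        half = len(ids) // 2
        p1 = group_portrait(model, ids[:half])
        p2 = group_portrait(model, ids[half:])
        whole = group_portrait(model, ids)
        w1 = half / len(ids)
        assert np.allclose(w1 * p1 + (1 - w1) * p2, whole, atol=1e-12)

    def test_empty_group_rejected(self, trained):
        _, model = trained
        with pytest.raises(ValueError):
            group_portrait(model, [])


class TestOverexpressionClusters:
    def test_unique_maximum_sample_is_flagged(self, trained):
        _, model = trained
        areas = overexpression_clusters(model, threshold=0.95)
        u = 0
        j = int(np.argmax(model.codebook[u]))
        assert areas.flags.iloc[u, j]

    def test_constant_metagene_never_flagged(self, trained):
        _, model = trained
        model2 = type(model)(grid=model.grid,
                             codebook=model.codebook.copy(),
                             sample_ids=model.sample_ids,
                             gene_ids=model.gene_ids, bmu=model.bmu,
                             seed=0,
                             quantization_errors=model.quantization_errors)
        model2.codebook[5] = 1.0
        areas = overexpression_clusters(model2, threshold=0.95)
        assert not areas.flags.iloc[5].any()

    def test_clusters_partition_flagged_units(self, trained):
        _, model = trained
        areas = overexpression_clusters(model, threshold=0.95)
        flagged = np.flatnonzero(areas.flags.any(axis=1).to_numpy())
        in_clusters = sorted(
            u for units in areas.clusters["units"] for u in units)
        assert sorted(flagged.tolist()) == in_clusters
        assert (areas.cluster_of_unit[flagged] > 0).all()

    def test_threshold_validated(self, trained):
        _, model = trained
        with pytest.raises(ValueError):
            overexpression_clusters(model, threshold=1.5)


def brute_force_mst_weight(dist):
    """Minimum spanning-tree weight by exhaustive search over edge subsets."""
    n = len(dist)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() == n and nx.is_connected(g):
            w = sum(dist[i][j] for i, j in combo)
            best = min(best, w)
    return best


class TestCorrelationSpanningTree:
    def test_three_node_enumeration(self):
        """r(AB)=0.9, r(BC)=0.8, r(AC)=0.1 -> tree {AB, BC}."""
        rng = np.random.default_rng(8)
        base = rng.normal(size=50)
        # construct profiles with approximately the target correlations
        a = base
        b = 0.9 * base + np.sqrt(1 - 0.81) * rng.normal(size=50)
        # c correlates with b but barely with a: blend b's residual
        resid = (b - 0.9 * base) / np.sqrt(1 - 0.81)
        c = 0.8 * resid + 0.1 * base
        profiles = pd.DataFrame([a, b, c], index=["A", "B", "C"])
        r = np.corrcoef(profiles.to_numpy())
        assert r[0, 1] > r[1, 2] > r[0, 2]     # intended ordering holds
        tree = correlation_spanning_tree(profiles)
        assert set(map(frozenset, tree.graph.edges)) == {
            frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_duplicate_profile_joined_by_zero_edge(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 30))
        X[1] = X[0]
        profiles = pd.DataFrame(X, index=["A", "B", "C", "D"])
        tree = correlation_spanning_tree(profiles)
        assert tree.graph.has_edge("A", "B")
        assert tree.graph["A"]["B"]["weight"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_minimum_for_small_n(self):
        rng = np.random.default_rng(10)
        for n in (4, 5, 6, 7):
            profiles = pd.DataFrame(rng.normal(size=(n, 25)),
                                    index=[f"N{i}" for i in range(n)])
            tree = correlation_spanning_tree(profiles)
            R = np.corrcoef(profiles.to_numpy())
            dist = 1.0 - R
            assert tree.total_weight() == pytest.approx(
                brute_force_mst_weight(dist), abs=1e-9)
            assert tree.graph.number_of_edges() == n - 1
            assert nx.is_connected(tree.graph)

    def test_constant_profile_names_the_node(self):
        X = np.random.default_rng(11).normal(size=(3, 20))
        X[2] = 5.0
        with pytest.raises(ValueError, match="N2"):
            correlation_spanning_tree(
                pd.DataFrame(X, index=["N0", "N1", "N2"]))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(6, 30))
        t1 = correlation_spanning_tree(
            pd.DataFrame(X, index=[f"A{i}" for i in range(6)]))
        t2 = correlation_spanning_tree(
            pd.DataFrame(X, index=[f"Z{i}" for i in range(6)]))
        e1 = {frozenset((u[1:], v[1:])) for u, v in t1.graph.edges}
        e2 = {frozenset((u[1:], v[1:])) for u, v in t2.graph.edges}
        assert e1 == e2


class TestDecomposeBranches:
    def test_star_with_three_leaves(self):
        g = nx.Graph([("hub", "a"), ("hub", "b"), ("hub", "c")])
        nx.set_edge_attributes(g, 1.0, "weight")
        from melspat.som_trajectory import CorrelationTree
        labels = decompose_branches(CorrelationTree(graph=g))
        assert labels["hub"] == "branch_point"
        assert len({labels["a"], labels["b"], labels["c"]}) == 3

    def test_path_graph_single_branch(self):
        g = nx.path_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        from melspat.som_trajectory import CorrelationTree
        labels = decompose_branches(CorrelationTree(graph=g))
        assert set(labels.values()) == {"branch_1"}

    def test_override_wins(self):
        g = nx.path_graph(3)
        from melspat.som_trajectory import CorrelationTree
        labels = decompose_branches(CorrelationTree(graph=g),
                                    override={0: "root"})
        assert labels[0] == "root"

    def test_three_armed_factor_structure_recovered(self):
        """Microregions from three planted factor arms largely share branch
        labels on the CST built from SOM metagene profiles."""
        arm = np.repeat([0, 1, 2], 20)
        prog = np.where(arm == 0, 0.1, 0.9) + np.random.default_rng(0).normal(
            0, 0.03, 60)
        infl = np.where(arm == 2, 0.9, 0.1) + np.random.default_rng(1).normal(
            0, 0.03, 60)
        cfg = ExpressionSimConfig(
            seed=13, n_microregions=60, n_genes=400, loading_scale=2.0,
            progression=np.clip(prog, 0, 1),
            inflammation=np.clip(infl, 0, 1))
        matrix, _ = simulate_expression(cfg)
        model = train_som(preprocess_expression(matrix), grid=(10, 10),
                          seed=0)
        tree = correlation_spanning_tree(metagene_profiles(model))
        labels = decompose_branches(tree, n_branches=3)
        mr_arm = dict(zip(matrix.microregion_ids, arm))
        purity = []
        for a in (0, 1, 2):
            members = [m for m in tree.nodes if mr_arm[m] == a]
            counts = pd.Series([labels[m] for m in members]).value_counts()
            purity.append(counts.iloc[0] / len(members))
        assert np.mean(purity) >= 0.9

    def test_heavy_edge_cut_separates_tight_clusters(self):
        rng = np.random.default_rng(14)
        centers = rng.normal(size=(3, 40)) * 5
        X = np.vstack([c + rng.normal(0, 0.2, size=(5, 40)) for c in centers])
        profiles = pd.DataFrame(X, index=[f"N{i:02d}" for i in range(15)])
        tree = correlation_spanning_tree(profiles)
        labels = decompose_branches(tree, n_branches=3)
        got = [sorted(n for n, l in labels.items() if l == b)
               for b in sorted(set(labels.values()))]
        expected = [[f"N{i:02d}" for i in range(j * 5, j * 5 + 5)]
                    for j in range(3)]
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))
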