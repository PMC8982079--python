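"""Spatial graph, Moran's I vs double-sum oracle, SVG test, modules,
k-means regions, DEG, gradient trend."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import region_module_truth
from stereopipe import spatial, synthetic
from stereopipe.matrix import ValidationError
from stereopipe.spatial import (
    build_knn_graph,
    deg_between,
    detect_modules,
    gradient_check,
    kmeans_regions,
    module_scores,
    morans_i,
    normalize_counts,
    svg_test,
)


def morans_double_sum(values, graph):
    """Explicit O(n^2) oracle: I = sum_ij w_ij z_i z_j / sum z_i^2."""
    z = np.asarray(values, float) - np.mean(values)
    W = graph.to_sparse().toarray()
    num = sum(
        W[i, j] * z[i] * z[j]
        for i in range(len(z))
        for j in range(len(z))
    )
    return num / (z @ z)


class TestKnnGraph:
    def test_three_collinear_bins_k1(self):
        pos = np.array([[0, 0], [1, 0], [3, 0]])
        g = build_knn_graph(pos, k=1)
        assert g.neighbors[0, 0] == 1  # endpoint picks the middle
        assert g.neighbors[1, 0] == 0  # middle picks the nearer endpoint
        assert g.neighbors[2, 0] == 1

    def test_row_sums_one_and_no_self(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 50, size=(40, 2)).astype(float)
        pos = np.unique(pos, axis=0)
        g = build_knn_graph(pos, k=5)
        assert np.allclose(g.weights.sum(axis=1), 1.0)
        assert all(i not in g.neighbors[i] for i in range(g.n))

    def test_k_equals_n_minus_1_fully_connected(self):
        pos = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        g = build_knn_graph(pos, k=3)
        for i in range(4):
            assert set(g.neighbors[i]) == set(range(4)) - {i}

    def test_ties_broken_lexicographically(self):
        # bin at origin equidistant from (1,0) and (0,1): (0,1) wins lexsort on (x,y)
        pos = np.array([[0, 0], [1, 0], [0, 1]], float)
        g = build_knn_graph(pos, k=1)
        assert g.neighbors[0, 0] == 2  # (0,1) sorts before (1,0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError):
            build_knn_graph(np.array([[0, 0], [1, 1]], float), k=2)


class TestMoransI:
    def test_four_bin_worked_example_matches_oracle(self):
        pos = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float)
        g = build_knn_graph(pos, k=2)
        values = np.array([1.0, 2.0, 3.0, 4.0])
        oracle = morans_double_sum(values, g)
        assert morans_i(values, g) == pytest.approx(oracle, abs=1e-14)
        assert oracle == pytest.approx(0.1)

    def test_matches_double_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(8, 30))
            pos = rng.normal(size=(n, 2)) * 10
            g = build_knn_graph(pos, k=int(rng.integers(1, min(6, n - 1) + 1)))
            v = rng.normal(size=n)
            assert abs(morans_i(v, g) - morans_double_sum(v, g)) < 1e-12

    def test_permutation_mean_is_classical_null_expectation(self):
        # exact enumeration over all 4! permutations: E[I] = -1/(n-1)
        pos = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float)
        g = build_knn_graph(pos, k=2)
        values = np.array([1.0, 2.0, 3.0, 4.0])
        mean_i = np.mean(
            [morans_i(values[list(p)], g) for p in itertools.permutations(range(4))]
        )
        assert mean_i == pytest.approx(-1 / 3, abs=1e-12)

    def test_smooth_gradient_strongly_positive(self):
        yy, xx = np.mgrid[0:20, 0:20]
        pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        g = build_knn_graph(pos, k=8)
        assert morans_i(yy.ravel().astype(float), g) > 0.5

    def test_constant_input_rejected(self):
        pos = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float)
        g = build_knn_graph(pos, k=2)
        with pytest.raises(ValidationError):
            morans_i(np.ones(4), g)


@pytest.fixture(scope="module")
def dense_working(working_matrix):
    bins, genes, X = working_matrix.to_dense()
    graph = build_knn_graph(bins[["x", "y"]].to_numpy(), k=15)
    return bins, genes, X, graph


class TestSvgTest:
    def test_planted_markers_significant(self, dense_working):
        bins, genes, X, graph = dense_working
        table = svg_test(X, graph, n_perm=500, seed=1, genes=genes).set_index("gene")
        markers = sorted({g for m in synthetic.TYPE_MARKERS.values() for g in m})
        assert (table.loc[markers, "q"] < 0.05).all()

    def test_constant_gene_flagged_untestable(self, dense_working):
        bins, genes, X, graph = dense_working
        X2 = np.column_stack([X, np.zeros(len(X))])
        table = svg_test(X2, graph, n_perm=100, seed=1, genes=list(genes) + ["flat"])
        row = table.set_index("gene").loc["flat"]
        assert not row["testable"]
        assert np.isnan(row["moran_i"])

    def test_q_dominates_p(self, dense_working):
        bins, genes, X, graph = dense_working
        table = svg_test(X, graph, n_perm=200, seed=2, genes=genes)
        ok = table["testable"]
        assert (table.loc[ok, "q"] >= table.loc[ok, "p"] - 1e-12).all()

    def test_ranking_stable_when_permutations_doubled(self, dense_working):
        bins, genes, X, graph = dense_working
        z1 = svg_test(X, graph, n_perm=500, seed=3, genes=genes).set_index("gene")["z"]
        z2 = svg_test(X, graph, n_perm=1000, seed=4, genes=genes).set_index("gene")["z"]
        both = pd.concat([z1, z2], axis=1).dropna()
        rho = stats.spearmanr(both.iloc[:, 0], both.iloc[:, 1]).statistic
        assert rho > 0.95

    def test_deterministic_for_fixed_seed(self, dense_working):
        bins, genes, X, graph = dense_working
        a = svg_test(X, graph, n_perm=120, seed=9, genes=genes)
        b = svg_test(X, graph, n_perm=120, seed=9, genes=genes)
        pd.testing.assert_frame_equal(a, b)


class TestModules:
    def test_planted_marker_modules_recovered_exactly(self, dense_working):
        bins, genes, X, graph = dense_working
        table = svg_test(X, graph, n_perm=500, seed=1, genes=genes).set_index("gene")
        sig = table[(table["testable"]) & (table["q"] < 0.05)].index.tolist()
        mods = detect_modules(sig, X, graph, genes=genes)
        found = {frozenset(gs) for gs in mods.modules.values()}
        truth_groups = region_module_truth()
        for region in ("bronchiole", "vessel", "immune"):
            assert truth_groups[region] in found
        # ARI over the planted region-marker groups is exact
        marker_truth = {g: r for r, gs in truth_groups.items() for g in gs}
        labels = mods.labels()
        shared = [g for g in marker_truth if g in labels]
        ari = adjusted_rand_score(
            [marker_truth[g] for g in shared], [labels[g] for g in shared]
        )
        assert ari == pytest.approx(1.0)

    def test_identical_genes_form_one_module(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:10, 0:10]
        pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        graph = build_knn_graph(pos, k=6)
        base = rng.poisson(5.0 + 3.0 * (yy.ravel() > 5), size=100).astype(float)
        X = np.column_stack([base + rng.poisson(0.5, 100) for _ in range(4)])
        mods = detect_modules([f"g{i}" for i in range(4)], X, graph,
                              genes=[f"g{i}" for i in range(4)])
        assert len(mods.modules) == 1

    def test_anticorrelated_genes_never_co_module(self):
        yy, xx = np.mgrid[0:10, 0:10]
        pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        graph = build_knn_graph(pos, k=6)
        up = (yy.ravel() * 2.0) + 1
        down = up.max() - up + 1
        X = np.column_stack([up, up, down, down]).astype(float)
        mods = detect_modules(list("abcd"), X, graph, genes=list("abcd"),
                              threshold=0.3)
        labels = mods.labels()
        if "a" in labels and "c" in labels:
            assert labels["a"] != labels["c"]

    def test_requires_two_genes(self, dense_working):
        bins, genes, X, graph = dense_working
        with pytest.raises(ValidationError):
            detect_modules(["Sftpc"], X, graph, genes=genes)


class TestModuleScores:
    def test_single_gene_module_equals_gene_zscore(self, dense_working):
        bins, genes, X, graph = dense_working
        mods = spatial.GeneModuleSet(modules={1: ["Sftpc"]})
        scores = module_scores(X, mods, genes=genes)
        v = normalize_counts(X)[:, list(genes).index("Sftpc")]
        z = (v - v.mean()) / v.std()
        assert np.allclose(scores[1].to_numpy(), z)

    def test_duplicate_gene_module_matches_single(self, dense_working):
        bins, genes, X, graph = dense_working
        i = list(genes).index("Sftpc")
        X2 = np.column_stack([X, X[:, i]])
        g2 = list(genes) + ["Sftpc2"]
        single = module_scores(X2, spatial.GeneModuleSet(modules={1: ["Sftpc"]}), genes=g2)
        double = module_scores(
            X2, spatial.GeneModuleSet(modules={1: ["Sftpc", "Sftpc2"]}), genes=g2
        )
        assert np.allclose(single[1].to_numpy(), double[1].to_numpy())

    def test_columns_standardized(self, dense_working):
        bins, genes, X, graph = dense_working
        mods = spatial.GeneModuleSet(
            modules={1: sorted(synthetic.TYPE_MARKERS["Clara"]), 2: ["Sftpc", "Ager"]}
        )
        scores = module_scores(X, mods, genes=genes)
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(scores.to_numpy().std(axis=0), 1, atol=1e-9)

    def test_bronchiole_module_elevated_inside_ring(
        self, dense_working, default_truth_section
    ):
        bins, genes, X, graph = dense_working
        mods = spatial.GeneModuleSet(modules={1: sorted(synthetic.TYPE_MARKERS["Clara"])})
        scores = module_scores(X, mods, genes=genes)
        truth_labels = default_truth_section.truth.region_labels(10)
        merged = bins.merge(truth_labels, on=["x", "y"])
        inside = scores[1][(merged["region"] == "bronchiole").to_numpy()]
        outside = scores[1][(merged["region"] != "bronchiole").to_numpy()]
        t = stats.ttest_ind(inside, outside, alternative="greater")
        assert t.pvalue < 0.01

    def test_module_without_measured_genes_rejected(self, dense_working):
        bins, genes, X, graph = dense_working
        with pytest.raises(ValidationError):
            module_scores(
                X, spatial.GeneModuleSet(modules={1: ["NotAGene"]}), genes=genes
            )


class TestKmeansRegions:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.3, size=(60, 3))
        b = rng.normal(4, 0.3, size=(40, 3))
        return np.vstack([a, b]), np.array([0] * 60 + [1] * 40)

    def test_two_separated_blobs_recovered(self):
        S, truth = self._blobs()
        reg = kmeans_regions(S, k=2, seed=0)
        assert adjusted_rand_score(truth, reg.labels) == pytest.approx(1.0)

    def test_k1_gives_single_label_100_percent(self):
        S, _ = self._blobs()
        reg = kmeans_regions(S, k=1, seed=0)
        assert set(reg.labels) == {1}
        assert reg.percentages.loc[1] == pytest.approx(100.0)

    def test_same_seed_identical_labels(self):
        S, _ = self._blobs()
        a = kmeans_regions(S, k=3, seed=7)
        b = kmeans_regions(S, k=3, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_ordered_by_descending_size(self):
        S, _ = self._blobs()
        reg = kmeans_regions(S, k=2, seed=0)
        sizes = pd.Series(reg.labels).value_counts()
        assert sizes.loc[1] >= sizes.loc[2]

    def test_inertia_never_increases_with_more_restarts(self):
        S, _ = self._blobs(seed=3)
        i1 = kmeans_regions(S, k=4, seed=0, n_init=1).inertia
        i10 = kmeans_regions(S, k=4, seed=0, n_init=10).inertia
        assert i10 <= i1 + 1e-9

    def test_invariant_to_score_column_order(self):
        S, _ = self._blobs(seed=4)
        a = kmeans_regions(S, k=3, seed=1)
        b = kmeans_regions(S[:, ::-1], k=3, seed=1)
        assert adjusted_rand_score(a.labels, b.labels) == pytest.approx(1.0)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_regions(np.zeros((3, 2)), k=4, seed=0)

    def test_region_recovery_on_default_section(
        self, dense_working, default_truth_section
    ):
        bins, genes, X, graph = dense_working
        table = svg_test(X, graph, n_perm=500, seed=1, genes=genes).set_index("gene")
        sig = table[(table["testable"]) & (table["q"] < 0.05)].index.tolist()
        mods = detect_modules(sig, X, graph, genes=genes)
        scores = module_scores(X, mods, genes=genes)
        reg = kmeans_regions(scores, k=4, seed=0)
        truth_labels = default_truth_section.truth.region_labels(10)
        merged = bins.assign(label=reg.labels).merge(truth_labels, on=["x", "y"])
        assert adjusted_rand_score(merged["region"], merged["label"]) > 0.9


class TestDegBetween:
    def _two_cluster_data(self, seed=0, n_null=50):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * 30 + [2] * 30)
        X = rng.poisson(5.0, size=(60, n_null)).astype(float)
        excl = np.r_[rng.poisson(20.0, 30), np.zeros(30)]
        X = np.column_stack([excl, X])
        genes = ["exclusive"] + [f"null{i}" for i in range(n_null)]
        return X, labels, genes

    def test_exclusive_gene_tops_table_positive_lfc(self):
        X, labels, genes = self._two_cluster_data()
        table = deg_between(X, labels, 1, 2, genes=genes)
        assert table.iloc[0]["gene"] == "exclusive"
        assert table.iloc[0]["log2fc"] > 0

    def test_swapping_clusters_negates_log2fc(self):
        X, labels, genes = self._two_cluster_data(seed=1)
        fwd = deg_between(X, labels, 1, 2, genes=genes).set_index("gene")
        rev = deg_between(X, labels, 2, 1, genes=genes).set_index("gene")
        assert np.allclose(fwd["log2fc"], -rev.loc[fwd.index, "log2fc"])

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(11)
        labels = np.array([1] * 50 + [2] * 50)
        X = rng.poisson(5.0, size=(100, 200)).astype(float)
        genes = [f"n{i}" for i in range(200)]
        table = deg_between(X, labels, 1, 2, genes=genes)
        assert (table["p"] < 0.05).mean() <= 0.07

    def test_small_cluster_rejected(self):
        X, labels, genes = self._two_cluster_data()
        labels = labels.copy()
        labels[:28] = 2  # cluster 1 left with 2 bins
        with pytest.raises(ValidationError):
            deg_between(X, labels, 1, 2, genes=genes)


class TestGradientCheck:
    def test_planted_gradient_gene_positive_and_significant(self, working_matrix):
        out = gradient_check(working_matrix, "Malat1", axis="y", seed=0)
        assert out["rho"] > 0
        assert out["p"] < 0.01

    def test_mirrored_axis_negates_statistic(self, dense_working):
        bins, genes, X, graph = dense_working
        pos = bins[["x", "y"]].to_numpy().astype(float)
        mirrored = pos.copy()
        mirrored[:, 1] = mirrored[:, 1].max() - mirrored[:, 1]
        fwd = gradient_check(X, "Malat1", axis="y", positions=pos, genes=genes, seed=0)
        rev = gradient_check(
            X, "Malat1", axis="y", positions=mirrored, genes=genes, seed=0
        )
        assert fwd["rho"] == pytest.approx(-rev["rho"])

    def test_null_pvalues_uniform(self):
        # exchangeable genes on a lattice: KS against U(0,1) must not reject
        rng = np.random.default_rng(13)
        yy, xx = np.mgrid[0:10, 0:10]
        pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        X = rng.poisson(10.0, size=(100, 100)).astype(float)
        genes = [f"n{i}" for i in range(100)]
        pvals = [
            gradient_check(X, g, axis="y", positions=pos, genes=genes,
                           n_perm=500, seed=i)["p"]
            for i, g in enumerate(genes)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_unmeasured_gene_rejected(self, dense_working):
        bins, genes, X, graph = dense_working
        with pytest.raises(ValidationError):
            gradient_check(
                X, "NotAGene", positions=bins[["x", "y"]].to_numpy(), genes=genes
            )
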