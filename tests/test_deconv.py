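"""Cell-type deconvolution: reference filter, signatures, EM, recovery."""

import numpy as np
import pandas as pd
import pytest

from stereopipe import deconv, synthetic
from stereopipe.deconv import (
    CellTypeReference,
    build_signatures,
    deconvolve_section,
    estimate_weights,
    filter_reference,
)
from stereopipe.matrix import ValidationError


def _reference(counts=None, n_genes=12):
    genes = [f"g{i}" for i in range(n_genes)]
    prof = pd.DataFrame(0.0, index=genes, columns=["A", "B", "C"])
    prof.iloc[0:4, 0] = [2, 2, 6, 2]
    prof.iloc[4:8, 1] = 1.0
    prof.iloc[8:12, 2] = 1.0
    return CellTypeReference(
        profiles=prof, cell_counts=counts or {"A": 100, "B": 100, "C": 100}
    )


class TestFilterReference:
    def test_19_cells_removed_20_retained(self):
        ref = _reference(counts={"A": 19, "B": 20, "C": 100})
        out = filter_reference(ref, min_cells=20)
        assert out.types() == ["B", "C"]

    def test_all_removed_is_an_error(self):
        ref = _reference(counts={"A": 1, "B": 2, "C": 3})
        with pytest.raises(ValidationError):
            filter_reference(ref, min_cells=20)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            CellTypeReference(profiles=pd.DataFrame(), cell_counts={})


class TestBuildSignatures:
    def test_column_normalization(self):
        prof = pd.DataFrame({"T": [2.0, 2.0, 6.0]}, index=list("abc"))
        ref = CellTypeReference(profiles=prof, cell_counts={"T": 50})
        theta = build_signatures(ref)
        assert np.allclose(theta["T"], [0.2, 0.2, 0.6])

    def test_proportional_profiles_warn_collinear(self):
        prof = pd.DataFrame(
            {"T1": [1.0, 2.0, 3.0], "T2": [2.0, 4.0, 6.0]}, index=list("abc")
        )
        ref = CellTypeReference(profiles=prof, cell_counts={"T1": 50, "T2": 50})
        with pytest.warns(UserWarning, match="collinear"):
            theta = build_signatures(ref)
        assert np.allclose(theta["T1"], theta["T2"])

    def test_zero_profile_rejected(self):
        prof = pd.DataFrame({"T": [0.0, 0.0]}, index=list("ab"))
        ref = CellTypeReference(profiles=prof, cell_counts={"T": 50})
        with pytest.raises(ValidationError):
            build_signatures(ref)


class TestEstimateWeights:
    def test_single_source_recovery(self):
        ref = _reference()
        theta = build_signatures(ref)
        rng = np.random.default_rng(0)
        c = rng.poisson(10_000 * theta["A"].to_numpy())
        w, ll, ok = estimate_weights(c, theta.to_numpy())
        assert w[0] >= 0.99

    def test_even_mixture_of_disjoint_signatures(self):
        ref = _reference()
        theta = build_signatures(ref)[["B", "C"]].to_numpy()
        rng = np.random.default_rng(1)
        c = rng.poisson(2000 * (0.5 * theta[:, 0] + 0.5 * theta[:, 1]))
        w, ll, ok = estimate_weights(c, theta)
        assert abs(w[0] - 0.5) < 0.02 and abs(w[1] - 0.5) < 0.02

    def test_loglik_monotone_nondecreasing(self):
        ref = _reference()
        theta = build_signatures(ref).to_numpy()
        rng = np.random.default_rng(2)
        for _ in range(20):
            w_true = rng.dirichlet(np.ones(3))
            c = rng.poisson(500 * theta @ w_true)
            if c.sum() == 0:
                continue
            _, _, _, trace = estimate_weights(c, theta, return_trace=True)
            assert np.all(np.diff(trace) >= -1e-9)

    def test_simplex_invariant(self):
        ref = _reference()
        theta = build_signatures(ref).to_numpy()
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = rng.poisson(200 * theta @ rng.dirichlet(np.ones(3)))
            if c.sum() == 0:
                continue
            w, _, _ = estimate_weights(c, theta)
            assert (w >= 0).all()
            assert abs(w.sum() - 1) < 1e-9

    def test_long_run_matches_short_run_objective(self):
        ref = _reference()
        theta = build_signatures(ref).to_numpy()
        rng = np.random.default_rng(4)
        for _ in range(20):
            c = rng.poisson(1000 * theta @ rng.dirichlet(np.ones(3)))
            if c.sum() == 0:
                continue
            _, ll, _ = estimate_weights(c, theta, max_iter=500)
            _, ll_long, _ = estimate_weights(c, theta, max_iter=5000, tol=1e-12)
            assert abs(ll - ll_long) < 1e-6 * max(1.0, abs(ll_long))

    def test_zero_count_bin_rejected(self):
        ref = _reference()
        theta = build_signatures(ref).to_numpy()
        with pytest.raises(ValidationError):
            estimate_weights(np.zeros(12), theta)


class TestDeconvolveSection:
    def _well_separated(self, n_types=4, n_genes=40):
        genes = [f"g{i}" for i in range(n_genes)]
        prof = pd.DataFrame(0.0, index=genes, columns=[f"T{j}" for j in range(n_types)])
        block = n_genes // n_types
        for j in range(n_types):
            prof.iloc[j * block : (j + 1) * block, j] = 1.0
        ref = CellTypeReference(
            profiles=prof, cell_counts={t: 100 for t in prof.columns}
        )
        return genes, prof, ref

    def test_weight_rmse_below_005_at_1000_counts(self):
        genes, prof, ref = self._well_separated()
        theta = build_signatures(ref)
        rng = np.random.default_rng(5)
        W = rng.dirichlet(np.ones(4), size=100)
        X = synthetic.simulate_mixture_bins(theta, W, depth=1000, seed=6)
        res = deconvolve_section(X, ref, max_types=4, genes=genes)
        rmse = np.sqrt(np.mean((res.weights.to_numpy() - W) ** 2))
        assert rmse < 0.05

    def test_recovery_improves_with_depth(self):
        genes, prof, ref = self._well_separated()
        theta = build_signatures(ref)
        rng = np.random.default_rng(7)
        W = rng.dirichlet(np.ones(4), size=60)
        rmses = {}
        for depth in (100, 10_000):
            X = synthetic.simulate_mixture_bins(theta, W, depth=depth, seed=8)
            res = deconvolve_section(X, ref, max_types=4, genes=genes)
            rmses[depth] = np.sqrt(np.mean((res.weights.to_numpy() - W) ** 2))
        assert rmses[10_000] < rmses[100]

    def test_inactive_cap_equals_unconstrained_fit(self):
        genes, prof, ref = self._well_separated()
        theta = build_signatures(ref)
        rng = np.random.default_rng(9)
        W = rng.dirichlet(np.ones(4), size=20)
        X = synthetic.simulate_mixture_bins(theta, W, depth=500, seed=10)
        capped = deconvolve_section(X, ref, max_types=4, genes=genes)
        for i in range(len(X)):
            w_free, _, _ = estimate_weights(
                X[i], theta.to_numpy() / theta.to_numpy().sum(0)
            )
            assert np.allclose(capped.weights.iloc[i].to_numpy(), w_free, atol=1e-6)

    def test_cap_limits_selected_types(self):
        genes, prof, ref = self._well_separated()
        theta = build_signatures(ref)
        rng = np.random.default_rng(11)
        W = rng.dirichlet(np.ones(4), size=30)
        X = synthetic.simulate_mixture_bins(theta, W, depth=800, seed=12)
        res = deconvolve_section(X, ref, max_types=2, genes=genes)
        assert all(len(s) <= 2 for s in res.selected)
        assert np.allclose(res.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_cohoused_types_correlate_disjoint_anticorrelate(self):
        # types A and B planted in the same bins, C in the complement
        genes, prof, ref = self._well_separated(n_types=3, n_genes=30)
        theta = build_signatures(ref)
        n = 120
        W = np.zeros((n, 3))
        W[: n // 2, 0] = 0.55
        W[: n // 2, 1] = 0.45
        W[n // 2 :, 2] = 1.0
        # small floor keeps every bin populated
        W = (W + 0.02) / (W + 0.02).sum(axis=1, keepdims=True)
        X = synthetic.simulate_mixture_bins(theta, W, depth=600, seed=13)
        res = deconvolve_section(X, ref, max_types=3, genes=genes)
        corr = res.correlations
        assert corr.loc["T0", "T1"] > 0.5
        assert corr.loc["T0", "T2"] < -0.5

    def test_empty_bins_skipped_with_flag(self):
        genes, prof, ref = self._well_separated()
        X = np.vstack([np.zeros(40), np.full(40, 5.0)])
        res = deconvolve_section(X, ref, max_types=4, genes=genes)
        assert len(res.skipped_bins) == 1
        assert res.selected[0] == ()

    def test_mito_genes_excluded_from_fit(self, working_matrix, default_truth_section):
        panel = default_truth_section.gene_panel
        profiles = synthetic.cell_type_profiles(panel)
        expressed = profiles.index[profiles.sum(axis=1) > 0]
        ref = CellTypeReference(
            profiles=profiles.loc[expressed],
            cell_counts={t: 200 for t in profiles.columns},
        )
        res = deconvolve_section(working_matrix, ref, max_types=4)
        # weights on a simplex for every fitted bin
        fitted = res.weights.sum(axis=1) > 0
        assert np.allclose(res.weights[fitted].sum(axis=1), 1.0, atol=1e-9)

    def test_section_truth_recovery(self, working_matrix, default_truth_section):
        truth = default_truth_section.truth
        panel = default_truth_section.gene_panel
        profiles = synthetic.cell_type_profiles(panel)
        expressed = profiles.index[profiles.sum(axis=1) > 0]
        ref = CellTypeReference(
            profiles=profiles.loc[expressed],
            cell_counts={t: 200 for t in profiles.columns},
        )
        res = deconvolve_section(working_matrix, ref, max_types=4)
        tw = truth.cell_type_weights(10).reindex(
            pd.MultiIndex.from_frame(res.bins[["x", "y"]])
        )
        common = [t for t in res.weights.columns if t in tw.columns]
        rmse = np.sqrt(
            np.mean((res.weights[common].to_numpy() - tw[common].to_numpy()) ** 2)
        )
        assert rmse < 0.05
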