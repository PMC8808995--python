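"""Affinity kernel, spectral clustering, cluster-number selection, crosstabs."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

from gliaplex.profiles import IntensityMatrix
from gliaplex.states import (
    affinity_matrix,
    crosstab_states,
    display_scale,
    estimate_k,
    name_states,
    spectral_cluster,
    _normalized_laplacian,
)


def direct_kernel(X, K, mu):
    """Element-wise oracle for the scaled exponential similarity kernel."""
    D = squareform(pdist(X))
    n = len(X)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mk_i = np.sort(D[i][np.arange(n) != i])[:K].mean()
            mk_j = np.sort(D[j][np.arange(n) != j])[:K].mean()
            eps = (mk_i + mk_j + D[i, j]) / 3
            W[i, j] = np.exp(-D[i, j] ** 2 / (mu * eps**2))
    return W


class TestAffinity:
    def test_coincident_rows_have_unit_affinity(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0], [0.0, 0.0]])
        g = affinity_matrix(X, K=2)
        assert g.W[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula_on_five_points(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 3.0], [-1.0, 1.0]])
        g = affinity_matrix(X, K=2, mu=0.5)
        assert np.allclose(g.W, direct_kernel(X, K=2, mu=0.5))

    def test_symmetric_and_finite_on_random_input(self):
        rng = np.random.default_rng(0)
        g = affinity_matrix(rng.standard_normal((200, 7)), K=20)
        assert np.allclose(g.W, g.W.T)
        assert np.all(np.isfinite(g.W))
        assert np.all(np.diagonal(g.W) > 0)

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            affinity_matrix(np.zeros((5, 2)), K=5)


class TestSpectralCluster:
    def test_block_diagonal_recovers_blocks(self):
        W = np.zeros((20, 20))
        W[:10, :10] = 1.0
        W[10:, 10:] = 1.0
        labels = spectral_cluster(W, 2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_three_blobs_recovered_exactly(self):
        X, y = make_blobs(n_samples=180, centers=3, cluster_std=0.3, center_box=(-8, 8), random_state=4)
        g = affinity_matrix(X, K=15)
        labels = spectral_cluster(g, 3, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_row_permutation_permutes_labels(self):
        X, _ = make_blobs(n_samples=90, centers=3, cluster_std=0.3, center_box=(-8, 8), random_state=1)
        g = affinity_matrix(X, K=10)
        lab = spectral_cluster(g, 3, seed=0)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(X))
        g2 = affinity_matrix(X[perm], K=10)
        lab2 = spectral_cluster(g2, 3, seed=0)
        assert adjusted_rand_score(lab[perm], lab2) == 1.0

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(5)
        W = affinity_matrix(rng.standard_normal((80, 4)), K=10).W
        assert np.array_equal(spectral_cluster(W, 3, seed=9), spectral_cluster(W, 3, seed=9))

    def test_laplacian_spectrum_in_unit_interval(self):
        rng = np.random.default_rng(3)
        W = affinity_matrix(rng.standard_normal((60, 3)), K=10).W
        vals = np.linalg.eigvalsh(_normalized_laplacian(W))
        assert vals.min() > -1e-8
        assert vals.max() < 2 + 1e-8
        assert abs(vals.min()) < 1e-8


class TestEstimateK:
    def test_three_components_have_three_zero_eigenvalues(self):
        W = np.zeros((30, 30))
        for a, b in ((0, 10), (10, 20), (20, 30)):
            W[a:b, a:b] = 1.0
        eig, rot = estimate_k(W, k_range=range(2, 8))
        assert eig == 3
        assert rot == 3

    def test_planted_three_blob_affinity_selects_three(self):
        X, _ = make_blobs(n_samples=240, centers=3, cluster_std=0.4, center_box=(-8, 8), random_state=6)
        g = affinity_matrix(X, K=20)
        eig, rot = estimate_k(g, k_range=range(2, 9))
        assert eig == 3
        assert rot == 3

    def test_uniform_graph_degenerates_gracefully(self):
        W = np.ones((40, 40))
        eig, rot = estimate_k(W, k_range=range(2, 6))
        assert eig == 2

    def test_k_range_validated(self):
        with pytest.raises(ValueError):
            estimate_k(np.ones((10, 10)), k_range=range(1, 4))


class TestCrosstabAndDisplay:
    def test_pure_split_crosstab(self):
        states = ["homeostatic"] * 5 + ["reactive"] * 5
        dx = ["CTRL"] * 5 + ["AD"] * 5
        wd, ws, counts = crosstab_states(states, dx)
        assert wd.loc["CTRL", "homeostatic"] == 1.0
        assert wd.loc["AD", "reactive"] == 1.0
        assert counts.loc["CTRL", "homeostatic"] == 5

    def test_proportion_tables_are_stochastic(self):
        rng = np.random.default_rng(0)
        states = rng.choice(["homeostatic", "intermediate", "reactive"], 200)
        dx = rng.choice(["CTRL", "AD"], 200)
        wd, ws, _ = crosstab_states(states, dx)
        assert np.allclose(wd.sum(axis=1), 1.0)
        assert np.allclose(ws.sum(axis=0), 1.0)

    def test_display_scale_affine_to_0_100(self):
        df = pd.DataFrame({"homeostatic": [-1.0], "intermediate": [0.0], "reactive": [1.0]}, index=["GFAP"])
        out = display_scale(df)
        assert list(out.loc["GFAP"]) == [0.0, 50.0, 100.0]

    def test_display_scale_constant_row_becomes_50(self):
        df = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["GS"])
        with pytest.warns(UserWarning):
            out = display_scale(df)
        assert np.allclose(out.loc["GS"], 50.0)

    def test_display_scale_bounds_on_random_rows(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((5, 4)), index=[f"m{i}" for i in range(5)])
        out = display_scale(df)
        assert np.allclose(out.min(axis=1), 0.0)
        assert np.allclose(out.max(axis=1), 100.0)

    def test_reactive_label_has_highest_reactivity_score(self):
        rng = np.random.default_rng(2)
        markers = ["EAAT1", "EAAT2", "GFAP", "GS", "TSPO", "VIM", "YKL-40"]
        n = 90
        vals = rng.standard_normal((n, 7)) * 0.2
        cluster = np.repeat([0, 1, 2], 30)
        for mk in ("GFAP", "VIM", "YKL-40", "TSPO"):
            j = markers.index(mk)
            vals[cluster == 1, j] += 3.0  # cluster 1 is the reactive one
        X = IntensityMatrix(
            values=pd.DataFrame(vals, columns=markers),
            meta=pd.DataFrame({"subject": ["s"] * n}),
        )
        mapping = name_states(cluster, X, "astrocyte")
        assert mapping[1] == "reactive"
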