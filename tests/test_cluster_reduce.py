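import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from chronomix.core_io import ValidationError
from chronomix.cluster_reduce import (
    _elbow,
    assign_clusters,
    pca,
    scale_profiles,
    silhouette_profiles,
    soft_threshold_keep,
    spca,
    tune_components,
    tune_keepx,
)
from conftest import bump_profile, sigmoid_profile


def _archetype_matrix(rng, n_per=5, noise=0.0):
    """9 x 4*n_per matrix: sigmoid+, sigmoid-, bump+, bump- blocks.

    Steepness/width vary within blocks (wider for the bumps) so the two
    orthogonal patterns carry distinct variance and PCA cannot mix them.
    """
    t = np.linspace(0, 1, 9)
    ks = np.linspace(7, 13, n_per)
    ws = np.linspace(0.10, 0.22, n_per)
    cols, labels = [], []
    for c in range(4):
        for i in range(n_per):
            base = sigmoid_profile(t, ks[i]) if c < 2 else bump_profile(t, ws[i])
            if c % 2 == 1:
                base = -base
            cols.append(base + rng.normal(0, noise, t.size))
            labels.append(c)
    return np.column_stack(cols), np.array(labels)


def brute_force_silhouette(values, labels):
    """Independent O(n^2) silhouette with 1 - Spearman distance."""
    n = values.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = 1 - spearmanr(values[:, i], values[:, j])[0]
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i]
        )
        s[i] = (b - a) / max(a, b)
    return s, float(np.mean(s))


class TestPca:
    def test_rank_one_matrix_explained_by_one_component(self):
        t = np.linspace(0, 1, 9)
        X = np.column_stack([c * (t - 0.5) for c in (1.0, 2.0, -3.0, 0.5)])
        dec = pca(X, 2, scale=True)
        ratio = dec.explained_variance[0] / dec.explained_variance.sum()
        assert ratio > 1 - 1e-10

    def test_loadings_orthonormal_and_reconstruction_exact(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(9, 20))
        H = 8
        dec = pca(X, H, scale=True)
        np.testing.assert_allclose(dec.loadings.T @ dec.loadings, np.eye(H), atol=1e-10)
        # full-rank reconstruction against the centered, scaled matrix
        Xs = scale_profiles(X)
        np.testing.assert_allclose(dec.scores @ dec.loadings.T, Xs, atol=1e-8)
        # loadings agree with an eigendecomposition oracle up to sign
        evals, evecs = np.linalg.eigh(Xs.T @ Xs)
        order = np.argsort(evals)[::-1]
        for h in range(H):
            v = evecs[:, order[h]]
            dot = abs(float(v @ dec.loadings[:, h]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_patterns_separate_onto_components(self):
        rng = np.random.default_rng(1)
        X, labels = _archetype_matrix(rng, noise=0.01)
        dec = pca(X, 2)
        comp = np.argmax(np.abs(dec.loadings), axis=1)
        assert len(set(comp[labels <= 1])) == 1
        assert len(set(comp[labels >= 2])) == 1
        assert comp[0] != comp[-1]

    def test_constant_profile_named_in_error(self):
        X = np.column_stack([np.linspace(0, 1, 9), np.full(9, 2.0)])
        with pytest.raises(ValidationError, match="feature_1"):
            pca(X, 1, scale=True)


class TestSpca:
    def test_no_sparsity_limit_matches_pca(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 12))
        dec_pca = pca(X, 3)
        dec_spca = spca(X, 3, [12, 12, 12])
        for h in range(3):
            diff = np.min([
                np.max(np.abs(dec_spca.loadings[:, h] - s * dec_pca.loadings[:, h]))
                for s in (1, -1)
            ])
            assert diff < 1e-6

    def test_soft_threshold_keep_one(self):
        out = soft_threshold_keep(np.array([3.0, -1.0, 0.5]), 1)
        np.testing.assert_allclose(out, [2.0, 0.0, 0.0])

    def test_block_structure_selected(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 9)
        block = np.column_stack([sigmoid_profile(t) + rng.normal(0, 0.02, 9) for _ in range(5)])
        noise = rng.normal(0, 0.3, size=(9, 15))
        X = np.hstack([block, noise])
        dec = spca(X, 1, [5])
        assert set(np.flatnonzero(dec.loadings[:, 0])) == set(range(5))

    def test_nonzero_counts_match_keepx(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 10))
        dec = spca(X, 2, [3, 6])
        assert np.count_nonzero(dec.loadings[:, 0]) == 3
        assert np.count_nonzero(dec.loadings[:, 1]) == 6


class TestSilhouette:
    def test_perfectly_separated_anticorrelated_clusters(self):
        t = np.linspace(0, 1, 9)
        up = [sigmoid_profile(t, k) for k in (8, 10, 12)]
        X = np.column_stack(up + [-u for u in up])
        sil, avg = silhouette_profiles(X, [1, 1, 1, -1, -1, -1])
        assert avg == pytest.approx(1.0)
        np.testing.assert_allclose(sil, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 50))
        labels = rng.integers(0, 3, 50)
        sil, avg = silhouette_profiles(X, labels)
        sil_o, avg_o = brute_force_silhouette(X, labels)
        np.testing.assert_allclose(sil, sil_o, atol=1e-12)
        assert avg == pytest.approx(avg_o, abs=1e-12)

    def test_fewer_than_two_clusters_rejected(self):
        X = np.random.default_rng(6).normal(size=(9, 4))
        with pytest.raises(ValidationError):
            silhouette_profiles(X, [1, 1, 1, 1])


class TestAssignClusters:
    def test_four_archetype_groups_form_four_sign_clusters(self):
        rng = np.random.default_rng(7)
        X, labels = _archetype_matrix(rng, noise=0.01)
        dec = pca(X, 2)
        assignment = assign_clusters(dec, X)
        got = assignment.labels().to_numpy()
        # each true group maps to exactly one signed cluster and vice versa
        mapping = {}
        for lab, true in zip(got, labels):
            mapping.setdefault(true, set()).add(lab)
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == 4
        assert assignment.average_silhouette > 0.9

    def test_spca_unselected_features_excluded(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 20))
        dec = spca(X, 2, [2, 2])
        assignment = assign_clusters(dec, X)
        t = assignment.table
        assert (t["status"] == "unselected").sum() >= 16
        assert (t["component"] > 0).sum() <= 4

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(9)
        X, _ = _archetype_matrix(rng, noise=0.02)
        perm = rng.permutation(X.shape[1])
        a1 = assign_clusters(pca(X, 2), X).table
        a2 = assign_clusters(pca(X[:, perm], 2), X[:, perm]).table
        for i, p in enumerate(perm):
            assert a1.loc[p, "component"] == a2.loc[i, "component"]
            assert a1.loc[p, "sign"] == a2.loc[i, "sign"]


class TestTuning:
    def test_two_patterns_select_two_components(self):
        rng = np.random.default_rng(10)
        X, _ = _archetype_matrix(rng, noise=0.02)
        H, trace = tune_components(X, 4)
        assert H == 2
        assert len(trace) == 4

    def test_rank_one_data_selects_one_component(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1, 9)
        base = sigmoid_profile(t)
        X = np.column_stack(
            [s * base + rng.normal(0, 0.01, 9) for s in (1, 1, 1, -1, -1, -1)]
        )
        H, _ = tune_components(X, 3)
        assert H == 1

    def test_elbow_rule_on_published_style_trace(self):
        assert _elbow([2, 4, 6, 8], [0.95, 0.95, 0.94, 0.70], 0.05) == 6
        assert _elbow([2, 4, 6, 8], [0.9, 0.9, 0.9, 0.9], 0.05) == 8

    def test_keepx_recovers_planted_block_size(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 1, 9)
        base = sigmoid_profile(t)
        signs = [1, -1, 1, -1, 1]
        block = [
            s * a * base + rng.normal(0, 0.02, 9)
            for s, a in zip(signs, (1.0, 1.0, 0.97, 0.97, 0.94))
        ]
        noise = [rng.normal(0, 0.5, 9) for _ in range(15)]
        X = np.column_stack(block + noise)
        keepx, trace = tune_keepx(X, 1, list(range(2, 11)))
        assert abs(keepx[0] - 5) <= 1
        assert set(trace.columns) == {"component", "keepx", "average_silhouette"}
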