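import numpy as np
import pytest

from chronomix.core_io import ValidationError
from chronomix.cluster_reduce import scale_profiles
from chronomix.integrate_blocks import (
    DesignMatrix,
    assign_clusters_multiblock,
    multiblock_spls,
    spls,
    tune_keepx_blocks,
)
from conftest import bump_profile, sigmoid_profile


def _two_blocks(rng, p1=6, p2=5, noise=0.05):
    t = np.linspace(0, 1, 9)
    latent = sigmoid_profile(t)
    X = np.column_stack(
        [latent * (1 - 0.1 * i) + rng.normal(0, noise, 9) for i in range(p1)]
    )
    Y = np.column_stack(
        [latent * (1 - 0.1 * i) + rng.normal(0, noise, 9) for i in range(p2)]
    )
    return X, Y


class TestTwoBlockEquivalences:
    def test_no_sparsity_matches_cross_product_svd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(9, 7))
        Y = rng.normal(size=(9, 5))
        fact = spls(X, Y, H=1)
        Xs, Ys = scale_profiles(X), scale_profiles(Y)
        U, _, Vt = np.linalg.svd(Xs.T @ Ys)
        for load, ref in ((fact.loadings[0][:, 0], U[:, 0]), (fact.loadings[1][:, 0], Vt[0])):
            diff = min(np.max(np.abs(load - s * ref)) for s in (1, -1))
            assert diff < 1e-6

    def test_keepx_one_finds_best_covariance_pair(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 8))
        Y = rng.normal(size=(9, 6))
        fact = spls(X, Y, H=1, keepx=[1], keepy=[1])
        i = int(np.flatnonzero(fact.loadings[0][:, 0])[0])
        j = int(np.flatnonzero(fact.loadings[1][:, 0])[0])
        Xs, Ys = scale_profiles(X), scale_profiles(Y)
        C = np.abs(Xs.T @ Ys)
        assert C[i, j] == pytest.approx(C.max())

    def test_identical_blocks_fully_correlated_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 5))
        fact = spls(X, X.copy(), H=1)
        r = np.corrcoef(fact.scores[0][:, 0], fact.scores[1][:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_shared_latent_pattern_carriers_selected(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 1, 9)
        latent = sigmoid_profile(t)
        X = np.column_stack(
            [latent + rng.normal(0, 0.05, 9) for _ in range(3)]
            + [rng.normal(0, 1, 9) for _ in range(5)]
        )
        Y = np.column_stack(
            [latent + rng.normal(0, 0.05, 9) for _ in range(2)]
            + [rng.normal(0, 1, 9) for _ in range(4)]
        )
        fact = spls(X, Y, H=1, keepx=[3], keepy=[2])
        assert set(np.flatnonzero(fact.loadings[0][:, 0])) == {0, 1, 2}
        assert set(np.flatnonzero(fact.loadings[1][:, 0])) == {0, 1}

    def test_keepx_exceeding_width_rejected(self):
        rng = np.random.default_rng(4)
        X, Y = _two_blocks(rng)
        with pytest.raises(ValidationError, match="keepx"):
            spls(X, Y, H=1, keepx=[99])


class TestMultiblock:
    def test_objective_nondecreasing_trace(self):
        rng = np.random.default_rng(5)
        blocks = [rng.normal(size=(9, p)) for p in (6, 5, 4)]
        fact = multiblock_spls(blocks, DesignMatrix.fully_connected(3), H=2)
        for trace in fact.objective_traces:
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-8 * np.maximum(np.abs(trace[:-1]), 1))

    def test_unit_norm_loadings_and_deflation_orthogonality(self):
        rng = np.random.default_rng(6)
        blocks = [rng.normal(size=(9, p)) for p in (6, 5)]
        fact = multiblock_spls(blocks, DesignMatrix.fully_connected(2), H=3)
        for A in fact.loadings:
            np.testing.assert_allclose(np.linalg.norm(A, axis=0), 1.0, atol=1e-12)
        for S in fact.scores:
            G = S.T @ S
            off = G - np.diag(np.diag(G))
            assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(G))

    def test_zero_design_rejected(self):
        rng = np.random.default_rng(7)
        blocks = [rng.normal(size=(9, 4)), rng.normal(size=(9, 4))]
        with pytest.raises(ValidationError, match="design"):
            multiblock_spls(blocks, np.zeros((2, 2)), H=1)

    def test_mismatched_grids_instruct_reinterpolation(self):
        from chronomix.spline_model import ModeledMatrix

        b1 = ModeledMatrix(np.zeros((9, 2)) + np.linspace(0, 1, 9)[:, None],
                           np.linspace(0, 1, 9), ["a", "b"])
        b2 = ModeledMatrix(np.zeros((5, 2)) + np.linspace(0, 1, 5)[:, None],
                           np.linspace(0, 1, 5), ["c", "d"])
        with pytest.raises(ValidationError, match="re-interpolat"):
            multiblock_spls([b1, b2], DesignMatrix.fully_connected(2), H=1)

    def test_design_matrix_validation(self):
        with pytest.raises(ValidationError):
            DesignMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            DesignMatrix(np.array([[0.5, 1.0], [1.0, 0.0]]))


class TestMultiblockClusters:
    def test_cross_omic_features_co_assigned(self):
        rng = np.random.default_rng(8)
        t = np.linspace(0, 1, 9)
        latent, other = sigmoid_profile(t), bump_profile(t)
        X = np.column_stack(
            [latent + rng.normal(0, 0.03, 9) for _ in range(3)]
            + [other + rng.normal(0, 0.03, 9) for _ in range(3)]
        )
        Y = np.column_stack(
            [latent + rng.normal(0, 0.03, 9) for _ in range(2)]
            + [other + rng.normal(0, 0.03, 9) for _ in range(2)]
        )
        fact = spls(X, Y, H=2, keepx=[3, 3], keepy=[2, 2])
        assignment = assign_clusters_multiblock(fact, [X, Y])
        tab = assignment.table
        comp_sign = tab.apply(lambda r: (r["component"], r["sign"]), axis=1)
        # latent carriers from both blocks share one cluster
        latent_rows = [0, 1, 2, 6, 7]
        assert len(set(comp_sign.iloc[latent_rows])) == 1
        assert tab["component"].max() <= 2

    def test_at_most_two_h_clusters_per_component(self):
        rng = np.random.default_rng(9)
        blocks = [rng.normal(size=(9, 6)), rng.normal(size=(9, 6))]
        fact = multiblock_spls(blocks, DesignMatrix.fully_connected(2), H=2)
        assignment = assign_clusters_multiblock(fact, blocks)
        labels = assignment.table.query("component > 0")
        labels = labels["component"] * labels["sign"].map({"+": 1, "-": -1})
        assert set(labels).issubset({1, -1, 2, -2})

    def test_tuning_recovers_signature_sizes(self):
        rng = np.random.default_rng(10)
        t = np.linspace(0, 1, 9)
        latent = sigmoid_profile(t)
        sx = [1, -1, 1, -1, 1]
        X = np.column_stack(
            [s * latent + rng.normal(0, 0.02, 9) for s in sx]
            + [rng.normal(0, 0.6, 9) for _ in range(7)]
        )
        sy = [1, -1, 1]
        Y = np.column_stack(
            [s * latent + rng.normal(0, 0.02, 9) for s in sy]
            + [rng.normal(0, 0.6, 9) for _ in range(7)]
        )
        keepx, trace = tune_keepx_blocks(
            [X, Y], DesignMatrix.fully_connected(2), H=1, grid=list(range(2, 9))
        )
        assert abs(keepx[0][0] - 5) <= 1
        assert abs(keepx[1][0] - 3) <= 1
        assert {"block", "component", "keepx", "average_silhouette"} <= set(trace.columns)
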