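import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronomix.cluster_reduce import ClusterAssignment
from chronomix.core_io import ValidationError
from chronomix.proportionality import cluster_proportionality, phi_s
from chronomix.spline_model import ModeledMatrix


def _assignment(feature_ids, components, signs):
    table = pd.DataFrame({
        "feature_id": feature_ids,
        "component": components,
        "sign": signs,
        "loading_value": [0.5] * len(feature_ids),
        "silhouette": [0.9] * len(feature_ids),
        "status": ["assigned"] * len(feature_ids),
    })
    return ClusterAssignment(table=table, average_silhouette=0.9)


class TestPhiS:
    def test_identical_profiles_give_zero(self):
        x = np.array([0.3, 1.2, -0.5, 2.0])
        assert phi_s(x, x) == 0.0

    def test_constant_log_shift_gives_zero(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert phi_s(x, x + 3.7) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self):
        assert phi_s(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 4.0])) == \
            pytest.approx(1.0 / 9.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=9), rng.normal(size=9)
        assert abs(phi_s(x, y) - phi_s(y, x)) < 1e-15

    def test_degenerate_denominator_returns_nan(self):
        x = np.array([0.0, 1.0, 2.0])
        assert np.isnan(phi_s(x, -x))

    def test_short_profiles_rejected(self):
        with pytest.raises(ValidationError):
            phi_s(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestClusterProportionality:
    @staticmethod
    def _shift_copy_matrix(rng):
        """Two clusters of log-shift copies; unrelated across clusters."""
        t = np.linspace(0, 1, 9)
        a = np.sin(2 * np.pi * t)
        b = np.cos(3 * np.pi * t) + t
        cols, ids, comps, signs = [], [], [], []
        for i, shift in enumerate((0.0, 0.5, 1.0)):
            cols.append(a + shift)
            ids.append(f"a{i}")
            comps.append(1)
            signs.append("+")
        for i, shift in enumerate((0.0, 0.7, 1.3)):
            cols.append(b + shift)
            ids.append(f"b{i}")
            comps.append(1)
            signs.append("-")
        return ModeledMatrix(np.column_stack(cols), t, ids), ids, comps, signs

    def test_within_cluster_proportional_pairs_detected(self):
        rng = np.random.default_rng(0)
        matrix, ids, comps, signs = self._shift_copy_matrix(rng)
        report = cluster_proportionality(matrix, _assignment(ids, comps, signs))
        for _, row in report.per_cluster.iterrows():
            assert row["median_within"] == pytest.approx(0.0, abs=1e-12)
            assert row["median_outside"] > 0.1
            assert row["wilcoxon_p"] < 0.05
        assert set(report.per_cluster.columns) == {
            "cluster", "n_members", "median_within", "median_outside", "wilcoxon_p",
        }

    def test_label_permutation_shrinks_the_gap(self):
        rng = np.random.default_rng(1)
        matrix, ids, comps, signs = self._shift_copy_matrix(rng)
        true_report = cluster_proportionality(matrix, _assignment(ids, comps, signs))
        true_gap = (
            true_report.per_cluster["median_outside"]
            - true_report.per_cluster["median_within"]
        ).mean()
        gaps = []
        for _ in range(20):
            perm = rng.permutation(len(ids))
            rep = cluster_proportionality(
                matrix,
                _assignment(ids, [comps[p] for p in perm], [signs[p] for p in perm]),
            )
            gaps.append(
                (rep.per_cluster["median_outside"] - rep.per_cluster["median_within"])
                .mean()
            )
        assert np.mean(gaps) < true_gap / 2

    def test_single_cluster_outside_absent(self):
        t = np.linspace(0, 1, 9)
        cols = [np.sin(t * 6) + s for s in (0.0, 0.5, 1.0)]
        matrix = ModeledMatrix(np.column_stack(cols), t, ["x", "y", "z"])
        report = cluster_proportionality(
            matrix, _assignment(["x", "y", "z"], [1, 1, 1], ["+", "+", "+"])
        )
        row = report.per_cluster.iloc[0]
        assert np.isnan(row["median_outside"]) and np.isnan(row["wilcoxon_p"])
        assert row["median_within"] == pytest.approx(0.0, abs=1e-12)

    def test_log_requested_on_nonpositive_raises(self):
        t = np.linspace(0, 1, 9)
        matrix = ModeledMatrix(np.column_stack([t - 0.5, t + 1]), t, ["neg", "pos"])
        with pytest.raises(ValidationError, match="neg"):
            cluster_proportionality(
                matrix, _assignment(["neg", "pos"], [1, 1], ["+", "-"]),
                log_input=False,
            )

    def test_wilcoxon_p_decreases_with_separation(self):
        t = np.linspace(0, 1, 9)
        base = np.sin(2 * np.pi * t)
        other = np.cos(3 * np.pi * t)
        pvals = []
        for sep in (0.05, 0.5, 5.0):
            rng = np.random.default_rng(2)
            cols = [base + rng.normal(0, 0.3, 9) for _ in range(4)] + [
                base + sep * other + rng.normal(0, 0.3, 9) for _ in range(4)
            ]
            ids = [f"f{i}" for i in range(8)]
            matrix = ModeledMatrix(np.column_stack(cols), t, ids)
            rep = cluster_proportionality(
                matrix, _assignment(ids, [1] * 8, ["+"] * 4 + ["-"] * 4)
            )
            pvals.append(rep.per_cluster["wilcoxon_p"].iloc[0])
        assert pvals[0] > pvals[-1]
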