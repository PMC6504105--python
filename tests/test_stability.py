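import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radstab.stability import (
    PhaseFeatureTensor,
    categorize_cov,
    compute_cov,
    compute_cov_matrix,
    cov_heatmap_order,
    motion_magnitude,
    population_mean_cov,
    stability_table,
    summarize_groups,
)


def _cov_oracle(v):
    # independent arithmetic: explicit sums, not numpy std
    v = list(map(float, v))
    n = len(v)
    mean = sum(v) / n
    sd = (sum((x - mean) ** 2 for x in v) / (n - 1)) ** 0.5
    return abs(sd / mean) * 100.0


class TestComputeCov:
    def test_constant_series_is_zero(self):
        assert compute_cov([10] * 8) == 0.0

    def test_simple_arithmetic(self):
        assert compute_cov([9, 10, 11]) == pytest.approx(10.0, abs=1e-12)

    def test_sign_symmetry(self):
        assert compute_cov([-9, -10, -11]) == pytest.approx(10.0, abs=1e-12)

    def test_zero_mean_is_undefined_sentinel(self):
        assert np.isnan(compute_cov([-1.0, 1.0]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_cov([1.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(50, 10, size=8)
        assert compute_cov(v) == pytest.approx(_cov_oracle(v), abs=1e-10)

    @given(st.floats(0.1, 100), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(10, 20, size=8)
        assert compute_cov(v * c) == pytest.approx(compute_cov(v), rel=1e-9)

    def test_translation_changes_cov(self):
        v = np.array([9.0, 10, 11])
        assert compute_cov(v + 10) == pytest.approx(100 * np.std(v, ddof=1) / 20)

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(1, 100, size=(3, 8, 4))
        m = compute_cov_matrix(arr)
        for i in range(3):
            for j in range(4):
                assert m[i, j] == pytest.approx(compute_cov(arr[i, :, j]), abs=1e-12)


class TestPopulationMean:
    def test_plain_mean(self):
        m, ex = population_mean_cov(np.array([[5.0], [5.0], [5.0]]))
        assert m[0] == 5.0 and ex[0] == 0

    def test_mean_over_defined_subset(self):
        m, ex = population_mean_cov(np.array([[np.nan], [8.0], [12.0]]))
        assert m[0] == pytest.approx(10.0)
        assert ex[0] == 1

    def test_all_undefined_flagged(self):
        m, _ = population_mean_cov(np.full((3, 1), np.nan))
        assert np.isnan(m[0])


class TestCategorize:
    @pytest.mark.parametrize(
        "cov,cat,bin_",
        [
            (0.0, "VerySmall", "<=5"),
            (5.0, "VerySmall", "<=5"),
            (5.0000001, "Small", "5-10"),
            (10.0, "Small", "5-10"),
            (10.0000001, "Intermediate", "10-15"),
            (15.0, "Intermediate", "10-15"),
            (15.1, "Intermediate", "15-20"),
            (20.0, "Intermediate", "15-20"),
            (20.0000001, "Large", ">20"),
            (37.0, "Large", ">20"),
        ],
    )
    def test_boundaries_right_closed(self, cov, cat, bin_):
        assert categorize_cov(cov) == (cat, bin_)

    def test_undefined_goes_large(self):
        assert categorize_cov(float("nan")) == ("Large", ">20")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize_cov(-1.0)


class TestMotionMagnitude:
    def test_identical_points(self):
        assert motion_magnitude(np.zeros((8, 3))) == 0.0

    def test_three_four_five(self):
        pts = np.zeros((8, 3))
        pts[3] = [3, 4, 0]
        assert motion_magnitude(pts) == pytest.approx(5.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_brute_force_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-20, 20, size=(8, 3))
        best = max(
            np.linalg.norm(pts[i] - pts[j]) for i in range(8) for j in range(i + 1, 8)
        )
        assert motion_magnitude(pts) == pytest.approx(best, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            motion_magnitude(np.zeros((1, 3)))


def _toy_table(covs, motion=None):
    n_pat, n_feat = covs.shape
    tensor_vals = np.ones((n_pat, 3, n_feat))
    tensor = PhaseFeatureTensor(
        tensor_vals, [f"f{j}" for j in range(n_feat)], [f"P{i}" for i in range(n_pat)]
    )
    table = stability_table(tensor)
    table.individual_cov = pd.DataFrame(covs, index=tensor.patient_ids, columns=tensor.feature_names)
    if motion is not None:
        table.motion = pd.Series(motion, index=tensor.patient_ids)
    return table


class TestHeatmapOrder:
    def test_identical_columns_adjacent(self):
        rng = np.random.default_rng(3)
        covs = rng.uniform(0, 19, size=(6, 5))
        covs[:, 3] = covs[:, 0]  # duplicate column
        table = _toy_table(covs)
        order, _ = cov_heatmap_order(table)
        assert abs(order.index("f0") - order.index("f3")) == 1

    def test_patient_rows_sorted_by_motion(self):
        covs = np.random.default_rng(0).uniform(0, 10, size=(3, 4))
        table = _toy_table(covs, motion=[30.0, 1.0, 12.0])
        _, patients = cov_heatmap_order(table)
        assert patients == ["P1", "P2", "P0"]

    def test_complete_linkage_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        covs = rng.uniform(0, 15, size=(4, 5))
        table = _toy_table(covs)
        order, _ = cov_heatmap_order(table)

        # independent naive complete linkage on the same capped data
        data = np.minimum(covs, 20.0).T
        clusters = [[i] for i in range(5)]

        def cdist(a, b):
            return max(np.linalg.norm(data[i] - data[j]) for i in a for j in b)

        merges = []
        while len(clusters) > 1:
            best = min(
                ((i, j) for i in range(len(clusters)) for j in range(i + 1, len(clusters))),
                key=lambda ij: cdist(clusters[ij[0]], clusters[ij[1]]),
            )
            i, j = best
            merges.append((clusters[i], clusters[j]))
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [clusters[i] + clusters[j]]
        # the first naive merge pair must be adjacent in the dendrogram leaf order
        first = merges[0][0] + merges[0][1]
        pos = sorted(order.index(f"f{i}") for i in first)
        assert pos[1] - pos[0] == 1


class TestSummaries:
    def test_all_zero_cov_is_all_very_small(self):
        tensor = PhaseFeatureTensor(np.ones((4, 3, 5)), [f"f{j}" for j in range(5)], [f"P{i}" for i in range(4)])
        table = stability_table(tensor)
        summary = summarize_groups(table)
        all_row = summary[(summary["group"] == "all") & (summary["category"] == "VerySmall")]
        assert all_row["fraction"].iloc[0] == 1.0

    def test_counts_partition_feature_set(self):
        rng = np.random.default_rng(5)
        tensor = PhaseFeatureTensor(
            rng.uniform(1, 100, size=(5, 8, 12)), [f"f{j}" for j in range(12)], [f"P{i}" for i in range(5)]
        )
        summary = summarize_groups(stability_table(tensor))
        assert summary[summary["group"] == "all"]["count"].sum() == 12
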