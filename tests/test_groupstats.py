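"""Group variability, distances, ellipses and rank-sum testing."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

import morphogrid as mg
from morphogrid.gpa import AlignedSample
from morphogrid.groupstats import (
    GroupingError,
    item_dendrogram,
    mean_difference_colors,
    per_item_distances,
)


def exhaustive_rank_sum_p(x, y):
    """Exact two-sided p by full enumeration over all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    sums = [
        ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)
    ]
    sums = np.asarray(sums)
    extreme = np.abs(sums - mu) >= abs(observed - mu) - 1e-12
    return extreme.mean()


def make_aligned(X, names=None, sizes=None) -> AlignedSample:
    X = np.asarray(X, dtype=float)
    names = names or [f"it{i:02d}" for i in range(len(X))]
    return AlignedSample(
        names=list(names),
        aligned=X.reshape(len(X), -1, 3),
        consensus=X.reshape(len(X), -1, 3).mean(axis=0),
        centroid_sizes=np.ones(len(X)) if sizes is None else np.asarray(sizes),
        iterations=1,
    )


class TestGroupVariability:
    def test_identical_items_zero(self):
        X = np.tile(np.arange(12.0), (4, 1))
        assert mg.group_variability(X) == 0.0

    def test_two_items_give_half_distance(self, rng):
        a, b = rng.normal(size=(2, 30))
        d = np.linalg.norm(a - b)
        assert mg.group_variability(np.stack([a, b])) == pytest.approx(d / 2)

    def test_matches_direct_summation(self, rng):
        X = rng.normal(size=(9, 60))
        direct = np.mean(
            [np.linalg.norm(x - X.mean(axis=0)) for x in X]
        )
        assert mg.group_variability(X) == pytest.approx(direct, rel=1e-12)

    def test_permutation_invariant(self, rng):
        X = rng.normal(size=(7, 30))
        perm = rng.permutation(7)
        assert mg.group_variability(X[perm]) == pytest.approx(
            mg.group_variability(X), rel=1e-12
        )

    def test_invariant_under_common_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        X = rng.normal(size=(6, 10, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        assert mg.group_variability(X @ R.T) == pytest.approx(
            mg.group_variability(X), rel=1e-12
        )


class TestDimensionDecomposition:
    def test_x_only_variation(self, rng):
        X = np.zeros((6, 8, 3))
        X[:, :, 0] = rng.normal(size=(6, 8))
        np.testing.assert_allclose(
            mg.dimension_decomposition(X), [100.0, 0.0, 0.0], atol=1e-12
        )

    def test_isotropic_noise_near_equal_thirds(self, rng):
        X = rng.normal(size=(60, 400, 3))
        fractions = mg.dimension_decomposition(X)
        np.testing.assert_allclose(fractions, [100 / 3] * 3, atol=1.0)

    def test_always_sums_to_100(self, rng):
        for _ in range(10):
            X = rng.normal(size=(4, 5, 3)) * rng.uniform(0.1, 10, size=3)
            assert mg.dimension_decomposition(X).sum() == pytest.approx(
                100.0, abs=1e-9
            )

    def test_zero_variability_flagged(self):
        with pytest.raises(GroupingError, match="undefined"):
            mg.dimension_decomposition(np.ones((3, 4, 3)))


class TestGroupDistances:
    def test_translated_groups_at_known_distance(self, rng):
        base = rng.normal(size=(4, 10, 3))
        offset = np.zeros((10, 3))
        offset[:, 0] = 0.3
        X = np.concatenate([base, base + offset])
        aligned = make_aligned(X)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=aligned.names)
        matrix, _, newick = mg.group_mean_distances(aligned, labels)
        d = np.linalg.norm(offset)
        assert matrix.loc["a", "b"] == pytest.approx(d, rel=1e-12)
        assert matrix.loc["a", "a"] == 0.0
        assert newick.count(",") == 1

    def test_three_group_upgma_matches_hand_computation(self, rng):
        means = {"a": 0.0, "b": 1.0, "c": 5.0}
        X = np.stack([
            np.full((4, 3), means[g]) for g in ("a", "a", "b", "b", "c", "c")
        ])
        # tiny jitter so groups have 2 distinct members each
        X = X + rng.normal(scale=1e-9, size=X.shape)
        aligned = make_aligned(X)
        labels = pd.Series(list("aabbcc"), index=aligned.names)
        matrix, Z, _ = mg.group_mean_distances(aligned, labels)
        d_ab = matrix.loc["a", "b"]
        d_ac = matrix.loc["a", "c"]
        d_bc = matrix.loc["b", "c"]
        # UPGMA: first merge = closest pair at its distance; final merge
        # at the average of the two cross distances
        assert Z[0, 2] == pytest.approx(d_ab, rel=1e-6)
        assert Z[1, 2] == pytest.approx((d_ac + d_bc) / 2, rel=1e-6)

    def test_identical_groups_all_zero(self):
        X = np.tile(np.arange(30.0), (6, 1))
        aligned = make_aligned(X)
        labels = pd.Series(list("aabbcc"), index=aligned.names)
        matrix, _, _ = mg.group_mean_distances(aligned, labels)
        assert matrix.to_numpy().max() == 0.0

    def test_item_dendrogram_runs(self, rng):
        aligned = make_aligned(rng.normal(size=(5, 30)))
        Z, newick = item_dendrogram(aligned, aligned.names)
        assert Z.shape == (4, 4)
        assert newick.endswith(";")


class TestGroupMeanShape:
    def test_identical_items_all_colors_zero(self):
        X = np.tile(np.arange(24.0), (3, 1))
        aligned = make_aligned(X)
        labels = pd.Series(["g"] * 3, index=aligned.names)
        shape = mg.group_mean_shape(aligned, labels, "g")
        assert shape.landmark_variability.max() == 0.0

    def test_perturbed_landmark_gets_color_one(self, rng):
        X = np.tile(rng.normal(size=30), (5, 1)).reshape(5, 10, 3)
        X[:, 4, 2] += rng.normal(scale=2.0, size=5)  # one noisy landmark
        aligned = make_aligned(X)
        labels = pd.Series(["g"] * 5, index=aligned.names)
        shape = mg.group_mean_shape(aligned, labels, "g")
        assert np.argmax(shape.landmark_variability) == 4
        assert shape.landmark_variability[4] == pytest.approx(1.0)

    def test_single_dimension_restriction(self, rng):
        X = np.tile(rng.normal(size=30), (5, 1)).reshape(5, 10, 3)
        X[:, 2, 0] += rng.normal(scale=3.0, size=5)  # X-dimension noise
        aligned = make_aligned(X)
        labels = pd.Series(["g"] * 5, index=aligned.names)
        restricted = mg.group_mean_shape(aligned, labels, "g", dimension=2)
        assert restricted.landmark_variability[2] == pytest.approx(0.0, abs=1e-12)

    def test_item_distance_mean_equals_group_variability(self, rng):
        X = rng.normal(size=(7, 12, 3))
        aligned = make_aligned(X)
        labels = pd.Series(["g"] * 7, index=aligned.names)
        shape = mg.group_mean_shape(aligned, labels, "g")
        assert shape.item_distances.mean() == pytest.approx(
            mg.group_variability(X), rel=1e-12
        )

    def test_difference_colors_normalized(self, rng):
        a, b = rng.normal(size=(2, 10, 3))
        colors = mean_difference_colors(a, b)
        assert colors.max() == pytest.approx(1.0)
        assert colors.shape == (10,)


class TestConfidenceEllipse:
    def test_isotropic_sample_axes_match_chi2_quantile(self, rng):
        scores = rng.normal(size=(20000, 2))
        ellipse = mg.confidence_ellipse(scores, level=0.90)
        expected = np.sqrt(4.60517)  # chi2.ppf(0.9, 2)
        np.testing.assert_allclose(ellipse.semi_axes, expected, rtol=0.03)

    def test_collinear_scores_degenerate(self, rng):
        t = rng.normal(size=50)
        scores = np.column_stack([t, 2 * t])
        ellipse = mg.confidence_ellipse(scores)
        assert ellipse.degenerate
        assert ellipse.semi_axes[1] <= 1e-6 * ellipse.semi_axes[0]

    def test_rotation_equivariance(self, rng):
        scores = rng.normal(size=(200, 2)) @ np.diag([3.0, 1.0])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = mg.confidence_ellipse(scores)
        b = mg.confidence_ellipse(scores @ R.T)
        np.testing.assert_allclose(b.center, R @ a.center, atol=1e-12)
        np.testing.assert_allclose(b.semi_axes, a.semi_axes, rtol=1e-9)
        cos = abs(np.dot(R @ a.axes[:, 0], b.axes[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestWilcoxonRankSum:
    def test_small_example_exact(self):
        result = mg.wilcoxon_rank_sum([1, 2], [3, 4])
        assert result.rank_sum == 3
        assert result.p_value == pytest.approx(1 / 3)
        assert result.method == "exact"

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=5)
        a = mg.wilcoxon_rank_sum(x, y)
        b = mg.wilcoxon_rank_sum(y, x)
        total = (len(x) + len(y)) * (len(x) + len(y) + 1) / 2
        assert a.rank_sum + b.rank_sum == pytest.approx(total)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_all_identical_gives_p_one(self):
        result = mg.wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert result.p_value == 1.0

    def test_exact_vs_normal_agree_at_n10(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            exact = mg.wilcoxon_rank_sum(x, y)
            assert exact.method == "exact"
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(exact.p_value - approx) <= 0.02

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 5),
                                       (5, 5), (2, 10), (6, 6)])
    def test_exact_p_equals_full_enumeration(self, rng, n1, n2):
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            result = mg.wilcoxon_rank_sum(x, y)
            assert result.method == "exact"
            expected = exhaustive_rank_sum_p(x, y)
            assert result.p_value == pytest.approx(expected, abs=1e-12), (
                f"n1={n1} n2={n2}: enumeration over {comb(n1 + n2, n1)} "
                "assignments disagrees"
            )


class TestSignificanceTests:
    def _two_group_sample(self, rng, offset=0.0, scale2=1.0, n1=8, n2=6):
        base = rng.normal(size=(10, 3))
        g1 = base + rng.normal(scale=0.1, size=(n1, 10, 3))
        g2 = base + offset + rng.normal(scale=0.1 * scale2, size=(n2, 10, 3))
        X = np.concatenate([g1, g2])
        aligned = make_aligned(X, sizes=np.r_[np.ones(n1), np.ones(n2)])
        labels = pd.Series(["a"] * n1 + ["b"] * n2, index=aligned.names)
        return aligned, labels

    def test_identical_groups_all_p_near_one(self):
        X = np.tile(np.arange(30.0), (8, 1)) + np.tile(
            np.arange(8.0)[:, None], (1, 30)
        )
        aligned = make_aligned(np.concatenate([X[:4], X[:4]]))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=aligned.names)
        results = mg.significance_tests(aligned, labels, "a", "b")
        for r in results.values():
            assert r.p_value >= 0.9

    def test_mean_offset_detected_by_mean_shape_test(self, rng):
        aligned, labels = self._two_group_sample(rng, offset=0.4)
        results = mg.significance_tests(aligned, labels, "a", "b")
        assert results["mean_shape"].p_value < 0.01
        assert results["mean_shape"].n1 == results["mean_shape"].n2 == 14

    def test_dispersion_difference_detected_by_variability_test(self, rng):
        aligned, labels = self._two_group_sample(rng, scale2=3.0, n1=12, n2=12)
        results = mg.significance_tests(aligned, labels, "a", "b")
        assert results["variability"].p_value < 0.01

    def test_empty_group_rejected(self, rng):
        aligned, labels = self._two_group_sample(rng)
        with pytest.raises(GroupingError):
            mg.significance_tests(aligned, labels, "a", "missing")


class TestAttributeAssignment:
    def test_combination_attribute(self):
        frame = pd.DataFrame(
            {"attr1": ["basalt", "flint"], "attr2": ["big", "small"]},
            index=["B01", "F01"],
        )
        assignment = mg.AttributeAssignment(frame)
        combo = assignment.combination(["B01", "F01"])
        assert list(combo) == ["basalt/big", "flint/small"]

    def test_missing_labels_raise(self):
        frame = pd.DataFrame({"attr1": ["x"]}, index=["a"])
        assignment = mg.AttributeAssignment(frame)
        with pytest.raises(GroupingError, match="b"):
            assignment.column("attr1", ["a", "b"])

    def test_group_summaries_table(self, rng):
        X = rng.normal(size=(6, 30))
        aligned = make_aligned(X, sizes=np.arange(1.0, 7.0))
        labels = pd.Series(list("aaabbb"), index=aligned.names)
        table = mg.group_summaries(aligned, labels)
        assert table.loc["a", "n"] == 3
        assert table.loc["b", "mean_centroid_size"] == pytest.approx(5.0)
        direct = mg.group_variability(X[:3])
        assert table.loc["a", "variability"] == pytest.approx(direct)
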