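"""Assemblage variability analytics and significance testing.

All shape statistics operate on the flattened Procrustes coordinates of
an aligned sample: a group's shape variability is the mean Euclidean
distance of its members from the group mean shape, the decomposition by
physical dimension apportions the summed squared deviations among X, Y
and Z, and between-group structure is summarized by the Euclidean
distances between group mean shapes with a UPGMA dendrogram.

Hypotheses about two groups are tested with the Wilcoxon rank-sum test,
which needs no distributional assumptions and remains valid when the
number of coordinates far exceeds the number of items: the variability
test compares the two groups' own-mean distance sets, the mean-shape test
compares every item's distance to its own group mean against its distance
to the opposite group mean, and the size test compares the centroid-size
sets directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import chi2, mannwhitneyu, rankdata

from .gpa import AlignedSample


class GroupingError(ValueError):
    """Raised when attribute labels do not cover the analyzed items."""


@dataclass
class AttributeAssignment:
    """Per-item labels for up to two categorical attributes."""

    labels: pd.DataFrame  # index = item names, 1 or 2 columns

    def __post_init__(self) -> None:
        if not 1 <= self.labels.shape[1] <= 2:
            raise GroupingError("at most two attributes are supported")
        self.labels = self.labels.astype(str)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AttributeAssignment":
        return cls(frame.iloc[:, :2].copy())

    @property
    def attributes(self) -> list[str]:
        return list(self.labels.columns)

    def column(self, attribute: str, items: list[str]) -> pd.Series:
        if attribute == "combination":
            return self.combination(items)
        if attribute not in self.labels.columns:
            raise GroupingError(f"unknown attribute '{attribute}'")
        missing = [i for i in items if i not in self.labels.index]
        if missing:
            raise GroupingError(f"items without labels: {', '.join(missing)}")
        return self.labels.loc[items, attribute]

    def combination(self, items: list[str]) -> pd.Series:
        """The derived (attr1, attr2) combination attribute."""
        if self.labels.shape[1] < 2:
            raise GroupingError("combination attribute needs two attributes")
        a, b = self.labels.columns
        col_a = self.column(a, items)
        col_b = self.column(b, items)
        return pd.Series(
            [f"{x}/{y}" for x, y in zip(col_a, col_b)], index=col_a.index,
            name="combination",
        )


# ---------------------------------------------------------------------------
# variability

def group_variability(configs: np.ndarray) -> float:
    """Mean Euclidean distance of a group's items from the group mean.

    ``configs`` is (m, ...) — flattened internally.  Zero for a single
    item or identical items.
    """
    X = np.asarray(configs, dtype=float).reshape(len(configs), -1)
    return float(np.linalg.norm(X - X.mean(axis=0), axis=1).mean())


def per_item_distances(configs: np.ndarray, mean: np.ndarray | None = None) -> np.ndarray:
    """Each item's distance from a mean (the group's own mean by default)."""
    X = np.asarray(configs, dtype=float).reshape(len(configs), -1)
    mu = X.mean(axis=0) if mean is None else np.asarray(mean, dtype=float).ravel()
    return np.linalg.norm(X - mu, axis=1)


def dimension_decomposition(configs: np.ndarray) -> np.ndarray:
    """Percent of a group's shape variability caused by each dimension.

    Squared deviations from the group mean are summed per physical
    dimension (X, Y, Z); returned as percentages summing to 100.
    """
    X = np.asarray(configs, dtype=float).reshape(len(configs), -1, 3)
    if len(X) < 2:
        raise GroupingError("dimension decomposition needs at least 2 items")
    dev = X - X.mean(axis=0)
    ss = (dev**2).sum(axis=(0, 1))  # (3,)
    total = ss.sum()
    if total <= 0:
        raise GroupingError("zero total variability: decomposition undefined")
    return 100.0 * ss / total


def group_summaries(
    aligned: AlignedSample, labels: pd.Series
) -> pd.DataFrame:
    """Panel table: n items, shape variability, mean centroid size per group."""
    X = aligned.flattened()
    sizes = pd.Series(aligned.centroid_sizes, index=aligned.names)
    rows = {}
    for group, items in labels.groupby(labels).groups.items():
        idx = [aligned.names.index(i) for i in items]
        rows[group] = {
            "n": len(idx),
            "variability": group_variability(X[idx]),
            "mean_centroid_size": float(sizes.loc[list(items)].mean()),
        }
    return pd.DataFrame(rows).T.rename_axis("group").astype({"n": int})


# ---------------------------------------------------------------------------
# between-group structure

def _group_means(X: np.ndarray, names: list[str], labels: pd.Series):
    means = {}
    for group, items in labels.groupby(labels).groups.items():
        idx = [names.index(i) for i in items]
        means[str(group)] = X[idx].mean(axis=0)
    return means


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    if tree.is_leaf():
        return f"{leaf_names[tree.id]}:0;"
    inner = ",".join(recurse(child, tree.dist) for child in (tree.left, tree.right))
    return f"({inner});"


def group_mean_distances(
    aligned: AlignedSample, labels: pd.Series
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Distances between group mean shapes + UPGMA dendrogram.

    Returns (symmetric distance matrix, scipy linkage matrix, Newick
    string).  Merge heights in the linkage are UPGMA (average-linkage)
    heights on the mean-shape distances.
    """
    means = _group_means(aligned.flattened(), aligned.names, labels)
    groups = list(means)
    if len(groups) < 2:
        raise GroupingError("need at least 2 groups for mean distances")
    matrix = np.zeros((len(groups), len(groups)))
    for (i, a), (j, b) in combinations(enumerate(groups), 2):
        d = float(np.linalg.norm(means[a] - means[b]))
        matrix[i, j] = matrix[j, i] = d
    condensed = matrix[np.triu_indices(len(groups), k=1)]
    Z = linkage(condensed, method="average")
    frame = pd.DataFrame(matrix, index=groups, columns=groups)
    return frame, Z, _linkage_to_newick(Z, groups)


def item_dendrogram(
    aligned: AlignedSample, items: list[str]
) -> tuple[np.ndarray, str]:
    """UPGMA dendrogram of individual items within a group."""
    X = aligned.flattened()
    idx = [aligned.names.index(i) for i in items]
    sub = X[idx]
    condensed = np.array([
        float(np.linalg.norm(sub[i] - sub[j]))
        for i, j in combinations(range(len(idx)), 2)
    ])
    Z = linkage(condensed, method="average")
    return Z, _linkage_to_newick(Z, items)


@dataclass
class GroupMeanShape:
    """A group's mean shape with per-item distances and landmark coloring."""

    group: str
    mean: np.ndarray  # (k, 3)
    item_distances: pd.Series
    landmark_variability: np.ndarray  # (k,) in [0, 1]


def group_mean_shape(
    aligned: AlignedSample,
    labels: pd.Series,
    group: str,
    dimension: int | None = None,
) -> GroupMeanShape:
    """Mean configuration of one group with variability color values.

    Landmark j's variability is the mean squared deviation of its
    3-vector (or of one physical dimension if ``dimension`` is 0, 1 or 2)
    across the group's items, normalized to a maximum of 1.
    """
    items = [i for i in aligned.names if labels.get(i) == group]
    if not items:
        raise GroupingError(f"group '{group}' has no items")
    idx = [aligned.names.index(i) for i in items]
    sub = aligned.aligned[idx]  # (m, k, 3)
    mean = sub.mean(axis=0)
    dev = sub - mean
    if dimension is not None:
        var = (dev[..., dimension] ** 2).mean(axis=0)
    else:
        var = (dev**2).sum(axis=2).mean(axis=0)
    peak = var.max()
    colors = var / peak if peak > 0 else var
    distances = pd.Series(
        np.linalg.norm(dev.reshape(len(idx), -1), axis=1), index=items, name="distance"
    )
    return GroupMeanShape(
        group=group, mean=mean, item_distances=distances,
        landmark_variability=colors,
    )


def mean_difference_colors(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Per-landmark distance between two group means, normalized to max 1."""
    d = np.linalg.norm(
        np.asarray(mean_a).reshape(-1, 3) - np.asarray(mean_b).reshape(-1, 3), axis=1
    )
    peak = d.max()
    return d / peak if peak > 0 else d


# ---------------------------------------------------------------------------
# confidence ellipse

@dataclass
class ConfidenceEllipse:
    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,) major, minor
    axes: np.ndarray  # (2, 2) unit axis directions as columns
    level: float
    degenerate: bool = False


def confidence_ellipse(scores: np.ndarray, level: float = 0.90) -> ConfidenceEllipse:
    """Gaussian confidence ellipse of 2-D scores.

    The boundary is ``(x - mu)^T S^-1 (x - mu) = chi2_2(level)`` with
    sample mean and covariance; semi-axes are ``sqrt(chi2 * eigval)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2 or len(scores) < 3:
        raise ValueError("need an (n >= 3) x 2 score array")
    mu = scores.mean(axis=0)
    S = np.cov(scores, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = chi2.ppf(level, df=2)
    degenerate = bool(eigvals[-1] <= 1e-12 * max(eigvals[0], 1e-300))
    semi = np.sqrt(np.clip(eigvals, 0.0, None) * q)
    return ConfidenceEllipse(
        center=mu, semi_axes=semi, axes=eigvecs, level=level, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# rank-sum testing

@dataclass
class RankSumResult:
    rank_sum: float  # rank sum of the first sample (mid-ranks)
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal"


def wilcoxon_rank_sum(sample1: np.ndarray, sample2: np.ndarray) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Returns the first sample's rank sum (mid-ranks for ties) and the
    two-sided p-value: exact when the pooled size is at most 20 and
    tie-free, otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(sample1, dtype=float).ravel()
    y = np.asarray(sample2, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rank_sum = float(ranks[: len(x)].sum())
    if np.ptp(pooled) == 0:
        return RankSumResult(rank_sum, 1.0, len(x), len(y), "degenerate")
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(pooled) <= 20:
        method = "exact"
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal"
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return RankSumResult(rank_sum, float(min(res.pvalue, 1.0)), len(x), len(y), method)


def significance_tests(
    aligned: AlignedSample,
    labels: pd.Series,
    group_a: str,
    group_b: str,
) -> dict[str, RankSumResult]:
    """The three two-group tests: variability, mean shape, centroid size.

    - variability: group A's own-mean distances vs group B's;
    - mean shape: every item's distance to its OWN group mean vs its
      distance to the OPPOSITE group mean (pooled across both groups);
    - size: the two groups' centroid-size sets.
    """
    X = aligned.flattened()
    idx_a = [i for i, n in enumerate(aligned.names) if labels.get(n) == group_a]
    idx_b = [i for i, n in enumerate(aligned.names) if labels.get(n) == group_b]
    if not idx_a or not idx_b:
        raise GroupingError(
            f"empty group among '{group_a}' ({len(idx_a)}) and "
            f"'{group_b}' ({len(idx_b)})"
        )
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise GroupingError("significance tests need at least 2 items per group")
    A, B = X[idx_a], X[idx_b]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)

    own_a = per_item_distances(A)
    own_b = per_item_distances(B)
    variability = wilcoxon_rank_sum(own_a, own_b)

    own = np.concatenate([own_a, own_b])
    opposite = np.concatenate(
        [per_item_distances(A, mean_b), per_item_distances(B, mean_a)]
    )
    mean_shape = wilcoxon_rank_sum(own, opposite)

    sizes = aligned.centroid_sizes
    size = wilcoxon_rank_sum(sizes[idx_a], sizes[idx_b])

    return {"variability": variability, "mean_shape": mean_shape, "size": size}
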