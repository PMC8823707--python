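"""Kinetic-profile clustering and descriptive statistics.

Clustering operates on the full 14-dimensional concatenated replicate
profiles of complete-case proteins, without standardization: the log2
SILAC ratios are already on a common, histone-anchored scale.

Two complementary views are produced, as in the source analysis style:

* k-means (Hartigan-Wong) for a small number of broad kinetic groups,
  summarized by the fraction of variance explained (between-SS / total-SS);
* UPGMA (average-linkage) hierarchical clustering on Euclidean distances,
  cut at several heights to give coarse-to-fine granularities, with the
  ``X_/N`` naming convention (cluster X of a cut yielding N clusters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .quant import ENDCOURSE_TIMEPOINTS, QuantMatrix, timepoint_of


# -- k-means ---------------------------------------------------------------


@dataclass
class KMeansResult:
    """Best-of-restarts Hartigan-Wong k-means solution."""

    assignment: pd.Series  # protein -> cluster index (1..k)
    centroids: np.ndarray  # k x n_samples
    within_ss: float
    between_ss: float
    total_ss: float
    seed: int
    n_restarts: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def variance_explained(self) -> float:
        return self.between_ss / self.total_ss if self.total_ss > 0 else 0.0

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def labels(self) -> pd.Series:
        """Cluster names in the ``X_/N`` convention (N = k here)."""
        return self.assignment.map(lambda x: f"{x}_/{self.k}")


def _hartigan_wong(
    x: np.ndarray, k: int, rng: np.random.Generator, max_passes: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Hartigan-Wong run: optimal-transfer passes from a random start.

    Points are moved one at a time to the cluster that most reduces the
    total within-cluster sum of squares, using the exact size-corrected
    transfer cost n/(n+1)*d2(gain) vs n/(n-1)*d2(loss); centroids are
    updated incrementally after every move.
    """
    n = x.shape[0]
    centers = x[rng.choice(n, size=k, replace=False)].copy()
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    # guard against empty clusters from duplicate rows in the init
    for j in range(k):
        if not (assign == j).any():
            assign[rng.integers(0, n)] = j
    counts = np.bincount(assign, minlength=k).astype(float)
    centers = np.vstack([x[assign == j].mean(axis=0) for j in range(k)])
    return _refine(x, assign, centers, counts, max_passes=max_passes)


def kmeans_profiles(
    m: QuantMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    init_assignment: np.ndarray | None = None,
) -> KMeansResult:
    """Hartigan-Wong k-means on complete kinetic profiles, best of restarts.

    ``init_assignment`` optionally adds one extra run warm-started from the
    given labeling (used by the variance-explained curve to guarantee
    monotonicity in k).

    Raises
    ------
    ValueError
        If k is out of range, the matrix has missing values, or all
        profiles are identical (no variance to partition).
    """
    if isinstance(m, QuantMatrix):
        if not m.is_complete():
            raise ValueError("k-means requires a complete matrix (no missing values)")
        x = m.values()
        index = m.proteins
    else:
        x = np.asarray(m, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    grand = x.mean(axis=0)
    total_ss = float(((x - grand) ** 2).sum())
    if k == 1:
        assign = np.zeros(n, dtype=int)
        return KMeansResult(
            assignment=pd.Series(assign + 1, index=index),
            centroids=grand[None, :],
            within_ss=total_ss,
            between_ss=0.0,
            total_ss=total_ss,
            seed=seed,
            n_restarts=n_restarts,
        )
    if total_ss == 0.0:
        raise ValueError("all profiles identical: k-means with k >= 2 is degenerate")
    if k == n:
        assign = np.arange(n)
        return KMeansResult(
            assignment=pd.Series(assign + 1, index=index),
            centroids=x.copy(),
            within_ss=0.0,
            between_ss=total_ss,
            total_ss=total_ss,
            seed=seed,
            n_restarts=n_restarts,
        )

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(max(1, n_restarts)):
        assign, centers, within = _hartigan_wong(x, k, rng)
        if best is None or within < best[2]:
            best = (assign, centers, within)
    if init_assignment is not None:
        assign = np.asarray(init_assignment, dtype=int).copy()
        if assign.shape != (n,) or np.bincount(assign, minlength=k).min() == 0:
            raise ValueError("init_assignment must label all points into k non-empty clusters")
        counts = np.bincount(assign, minlength=k).astype(float)
        centers = np.vstack([x[assign == j].mean(axis=0) for j in range(k)])
        assign2, centers2, within2 = _refine(x, assign, centers, counts)
        if best is None or within2 < best[2]:
            best = (assign2, centers2, within2)

    assign, centers, within = best
    # renumber clusters by first appearance in input order
    order: dict[int, int] = {}
    for a in assign:
        if a not in order:
            order[a] = len(order) + 1
    relabeled = np.array([order[a] for a in assign])
    centers = np.vstack([centers[[c for c, lab in order.items() if lab == j + 1][0]] for j in range(k)])
    between = total_ss - within
    return KMeansResult(
        assignment=pd.Series(relabeled, index=index),
        centroids=centers,
        within_ss=within,
        between_ss=between,
        total_ss=total_ss,
        seed=seed,
        n_restarts=n_restarts,
    )


def _refine(
    x: np.ndarray,
    assign: np.ndarray,
    centers: np.ndarray,
    counts: np.ndarray,
    max_passes: int = 50,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hartigan-Wong optimal-transfer passes from a given labeling.

    Points are moved one at a time to the cluster that most reduces the
    total within-cluster sum of squares, using the exact size-corrected
    transfer costs n/(n+1)*d2 (gain) vs n/(n-1)*d2 (loss); centroids are
    updated incrementally after every move.
    """
    n = x.shape[0]
    assign = assign.copy()
    centers = centers.copy()
    counts = counts.copy()
    for _ in range(max_passes):
        moved = 0
        for i in range(n):
            ci = assign[i]
            if counts[ci] <= 1:
                continue
            diff = centers - x[i]
            dist2 = np.einsum("ij,ij->i", diff, diff)
            removal_gain = counts[ci] / (counts[ci] - 1.0) * dist2[ci]
            cost = counts / (counts + 1.0) * dist2
            cost[ci] = np.inf
            cj = int(cost.argmin())
            if cost[cj] < removal_gain - 1e-12:
                centers[ci] = (centers[ci] * counts[ci] - x[i]) / (counts[ci] - 1.0)
                centers[cj] = (centers[cj] * counts[cj] + x[i]) / (counts[cj] + 1.0)
                counts[ci] -= 1.0
                counts[cj] += 1.0
                assign[i] = cj
                moved += 1
        if moved == 0:
            break
    within = float(((x - centers[assign]) ** 2).sum())
    return assign, centers, within


def variance_explained_curve(
    m: QuantMatrix | np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    n_restarts: int = 10,
) -> list[tuple[int, float]]:
    """Variance explained (between-SS / total-SS) as a function of k.

    Each k is solved with ``n_restarts`` random starts plus a warm start
    derived from the previous k's solution (splitting the point farthest
    from its centroid into a new cluster), which makes the curve
    non-decreasing in k.
    """
    ks = sorted(set(int(k) for k in k_range))
    results: list[tuple[int, float]] = []
    prev: KMeansResult | None = None
    for k in ks:
        init = None
        if prev is not None and prev.k == k - 1 and k >= 2:
            x = m.values() if isinstance(m, QuantMatrix) else np.asarray(m, dtype=float)
            assign0 = prev.assignment.to_numpy() - 1
            resid = ((x - prev.centroids[assign0]) ** 2).sum(axis=1)
            init = assign0.copy()
            init[int(resid.argmax())] = k - 1  # seed the new cluster
            if np.bincount(init, minlength=k).min() == 0:
                init = None
        res = kmeans_profiles(m, k, seed=seed + k, n_restarts=n_restarts, init_assignment=init)
        if results and res.variance_explained < results[-1][1]:
            # restarts can in principle land worse than the k-1 optimum;
            # the warm start above makes this unreachable, but keep the
            # guarantee explicit
            res = kmeans_profiles(
                m, k, seed=seed + k, n_restarts=n_restarts * 2, init_assignment=init
            )
        results.append((k, res.variance_explained))
        prev = res
    return results


# -- hierarchical clustering -----------------------------------------------


@dataclass
class ClusterTree:
    """UPGMA dendrogram over kinetic profiles.

    ``merges`` is the (n-1) x 4 linkage matrix (left, right, height, size)
    in scipy convention; heights are average inter-cluster Euclidean
    distances and are non-decreasing along the merge sequence.
    """

    merges: np.ndarray
    leaves: pd.Index  # protein IDs in input order

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("UPGMA merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths (height differences)."""
        root = to_tree(self.merges)
        names = list(self.leaves)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


@dataclass
class ClusterAssignment:
    """A tree cut: protein -> cluster at one granularity.

    Cluster names follow the ``X_/N`` convention, X numbered by order of
    first appearance in input order.
    """

    height: float
    n_clusters: int
    labels: pd.Series  # protein -> "X_/N"
    cluster_index: pd.Series  # protein -> X (int)

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("assignment labels proteins more than once")
        if self.cluster_index.nunique() != self.n_clusters:
            raise ValueError("cluster count inconsistent with labels")

    @property
    def sizes(self) -> pd.Series:
        return self.cluster_index.value_counts().sort_index()

    @property
    def n_singletons(self) -> int:
        return int((self.sizes == 1).sum())

    def members(self, cluster: int | str) -> pd.Index:
        if isinstance(cluster, str):
            sel = self.labels == cluster
        else:
            sel = self.cluster_index == cluster
        return self.labels.index[sel]


def build_tree(m: QuantMatrix | np.ndarray, leaves: pd.Index | None = None) -> ClusterTree:
    """UPGMA tree over pairwise Euclidean distances of complete profiles."""
    if isinstance(m, QuantMatrix):
        if not m.is_complete():
            raise ValueError("hierarchical clustering requires a complete matrix")
        x = m.values()
        leaves = m.proteins
    else:
        x = np.asarray(m, dtype=float)
        if leaves is None:
            leaves = pd.RangeIndex(x.shape[0]).astype(str)
    if x.shape[0] < 2:
        raise ValueError("need at least two profiles to build a tree")
    merges = linkage(pdist(x, metric="euclidean"), method="average")
    return ClusterTree(merges=merges, leaves=pd.Index(leaves))


def cut_tree(tree: ClusterTree, h: float) -> ClusterAssignment:
    """Partition the leaves by removing all merges above height ``h``.

    Merges at exactly ``h`` are kept (joined).  Clusters are renumbered by
    first appearance in input order and named ``X_/N``.
    """
    if h < 0:
        raise ValueError("cut height must be non-negative")
    raw = fcluster(tree.merges, t=h, criterion="distance")
    order: dict[int, int] = {}
    for r in raw:
        if r not in order:
            order[r] = len(order) + 1
    idx = np.array([order[r] for r in raw])
    n_clusters = len(order)
    labels = pd.Series([f"{i}_/{n_clusters}" for i in idx], index=tree.leaves)
    return ClusterAssignment(
        height=h,
        n_clusters=n_clusters,
        labels=labels,
        cluster_index=pd.Series(idx, index=tree.leaves),
    )


# -- descriptive statistics ------------------------------------------------


def _labels_of(a: ClusterAssignment | KMeansResult | pd.Series) -> pd.Series:
    if isinstance(a, ClusterAssignment):
        return a.labels
    if isinstance(a, KMeansResult):
        return a.labels()
    return a


def cluster_medians(
    m: QuantMatrix, a: ClusterAssignment | KMeansResult | pd.Series
) -> pd.DataFrame:
    """Per-cluster, per-sample median log2 ratio (clusters x samples)."""
    labels = _labels_of(a)
    if not labels.index.equals(m.proteins):
        labels = labels.reindex(m.proteins)
        if labels.isna().any():
            raise ValueError("assignment does not cover all matrix proteins")
    medians = m.ratios.groupby(labels).median()
    if medians.isna().to_numpy().any() and m.is_complete():
        raise ValueError("empty cluster in assignment")
    return medians


@dataclass
class TrendClassification:
    """Cluster -> overall trend during mitotic entry."""

    labels: pd.Series  # cluster -> {depleted, accumulated, minor-change}
    thresholds: tuple[float, float]
    endcourse_means: pd.Series

    def counts(self, sizes: pd.Series | None = None) -> pd.Series:
        """Number of clusters (or proteins, given cluster sizes) per trend."""
        if sizes is None:
            return self.labels.value_counts()
        df = pd.DataFrame({"trend": self.labels, "size": sizes.reindex(self.labels.index)})
        return df.groupby("trend")["size"].sum()


def classify_trends(
    medians: pd.DataFrame, thresholds: tuple[float, float] = (-0.58, 0.58)
) -> TrendClassification:
    """Classify clusters as depleted / accumulated / minor-change.

    The call uses the cluster's end-course level: the mean of its median
    log2 ratios over the 15-25 min samples (both replicates), where the
    time course has plateaued.  Defaults of +/-0.58 log2 correspond to a
    1.5-fold change.
    """
    lo, hi = thresholds
    if not (lo < 0 < hi):
        raise ValueError("thresholds must straddle zero: depletion_cut < 0 < accumulation_cut")
    end_cols = [c for c in medians.columns if timepoint_of(c) in ENDCOURSE_TIMEPOINTS]
    if not end_cols:
        raise ValueError("no end-course (15-25 min) samples in the median table")
    end = medians[end_cols].mean(axis=1)
    if not np.isfinite(end.to_numpy()).all():
        raise ValueError("non-finite cluster medians")
    labels = pd.Series(
        np.where(end <= lo, "depleted", np.where(end >= hi, "accumulated", "minor-change")),
        index=medians.index,
    )
    return TrendClassification(labels=labels, thresholds=(lo, hi), endcourse_means=end)


def timepoint_correlation(m: QuantMatrix, average_replicates: bool = True) -> pd.DataFrame:
    """Pearson correlation between time-point columns, computed over proteins."""
    if not m.is_complete():
        raise ValueError("correlation requires a complete matrix")
    data = m.ratios
    if average_replicates:
        tps = {}
        for c in data.columns:
            tps.setdefault(timepoint_of(c), []).append(c)
        data = pd.DataFrame({t: data[cols].mean(axis=1) for t, cols in tps.items()})
    stds = data.std(ddof=0)
    zero = [c for c in data.columns if stds[c] == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    corr = pd.DataFrame(
        np.corrcoef(data.to_numpy(), rowvar=False), index=data.columns, columns=data.columns
    )
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca_profiles(m: QuantMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centered PCA of the profiles: scores and explained-variance fractions."""
    from sklearn.decomposition import PCA

    if not m.is_complete():
        raise ValueError("PCA requires a complete matrix")
    x = m.values()
    if n_components > min(x.shape):
        raise ValueError(f"n_components={n_components} exceeds min(n, d)={min(x.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=m.proteins, columns=cols), pca.explained_variance_ratio_
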