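"""Unsupervised segmentation of MSI feature matrices.

Tissue subtypes are found by bisecting k-means with correlation distance
d(a, b) = 1 - Pearson r(a, b): pixels whose spectra have the same *shape*
cluster together regardless of overall intensity, which suits ion-count
data where section-to-section intensity scaling is nuisance.

The bisecting scheme repeatedly splits the largest cluster in two.  Splits
are mandatory while the largest cluster still holds more than ``max_share``
(default 40%) of all pixels; after that, splitting continues only while the
global Calinski-Harabasz (CH) score keeps strictly improving.  CH is
computed with ordinary Euclidean geometry on the feature matrix, the
standard definition of the index, even though the assignments themselves
use correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

__all__ = [
    "CorrelationKMeans",
    "BisectingKMeans",
    "ClusterImage",
    "correlation_kmeans",
    "bisecting_segmentation",
    "calinski_harabasz",
    "cluster_composition",
]


def _row_normalize(x: np.ndarray) -> np.ndarray:
    """Centre each row and scale to unit norm, so that 1 - corr = half squared distance."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"correlation distance undefined for constant feature vector(s) at "
            f"row index {bad[0]}"
        )
    return centered / norms


def _corr_dist(xn: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between normalised rows and raw centroids."""
    c = centers - centers.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(c, axis=1, keepdims=True)
    cn[cn == 0] = 1.0  # degenerate centroid: distance ~1 to everything
    c = c / cn
    return 1.0 - xn @ c.T


class CorrelationKMeans(ClusterMixin, BaseEstimator):
    """Lloyd k-means under correlation distance.

    Centroids are arithmetic means of member rows; assignment minimises
    1 - Pearson r(row, centroid).  Assignments are invariant to positive
    affine transforms of any row.  Best of ``n_init`` restarts by total
    within-cluster distance.

    Parameters
    ----------
    n_clusters : int
    n_init : int, default 10
    max_iter : int, default 100
    random_state : int, RandomState or None

    Attributes
    ----------
    labels_ : ndarray of int, shape (n_samples,)
    cluster_centers_ : ndarray, shape (n_clusters, n_features)
    inertia_ : float
        Sum of correlation distances of rows to their centroid.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 10, max_iter: int = 100,
                 random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds number of rows {X.shape[0]}"
            )
        rng = check_random_state(self.random_state)
        xn = _row_normalize(X)

        best = None
        for _ in range(self.n_init):
            labels, centers, inertia = self._lloyd(X, xn, rng)
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia)
        self.labels_, self.cluster_centers_, self.inertia_ = best
        return self

    def _lloyd(self, X, xn, rng):
        n = X.shape[0]
        centers = X[rng.choice(n, size=self.n_clusters, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(self.max_iter):
            dist = _corr_dist(xn, centers)
            new_labels = dist.argmin(axis=1)
            # reseed empty clusters with the worst-fit point
            for k in range(self.n_clusters):
                if not np.any(new_labels == k):
                    worst = dist[np.arange(n), new_labels].argmax()
                    new_labels[worst] = k
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for k in range(self.n_clusters):
                centers[k] = X[labels == k].mean(axis=0)
        dist = _corr_dist(xn, centers)
        inertia = float(dist[np.arange(n), labels].sum())
        return labels, centers, inertia

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        return _corr_dist(_row_normalize(X), self.cluster_centers_).argmin(axis=1)


def correlation_kmeans(X, k: int, restarts: int = 10, max_iter: int = 100, seed=None):
    """Functional wrapper; returns the label vector."""
    return CorrelationKMeans(
        n_clusters=k, n_init=restarts, max_iter=max_iter, random_state=seed
    ).fit(X).labels_


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: [B/(K-1)] / [W/(n-K)].

    B and W are between- and within-cluster sums of squared Euclidean
    deviations.  A zero within-cluster sum yields +inf.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("Calinski-Harabasz needs at least 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = X.mean(axis=0)
    b = 0.0
    w = 0.0
    for lab in uniq:
        members = X[labels == lab]
        mean = members.mean(axis=0)
        b += members.shape[0] * float(((mean - grand) ** 2).sum())
        w += float(((members - mean) ** 2).sum())
    if w == 0:
        import warnings

        warnings.warn("zero within-cluster scatter; CH index is infinite")
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


@dataclass
class ClusterImage:
    """Segmentation result: per-pixel labels in 1..K plus the split record."""

    labels: np.ndarray
    k: int
    partition_history: list[np.ndarray] = field(default_factory=list)
    ch_scores: dict[int, float] = field(default_factory=dict)

    def to_grid(self, coords: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Render labels on a 2D grid (NaN off the mask)."""
        rc = np.asarray(coords, dtype=int)
        if shape is None:
            shape = (rc[:, 0].max() + 1, rc[:, 1].max() + 1)
        grid = np.full(shape, np.nan)
        grid[rc[:, 0], rc[:, 1]] = self.labels
        return grid


class BisectingKMeans(ClusterMixin, BaseEstimator):
    """Bisecting correlation k-means with a largest-cluster stop rule.

    The largest cluster is split (k=2 correlation k-means) while it holds
    more than ``max_share`` of all pixels; afterwards splitting continues
    while the global CH score strictly increases, up to ``k_max`` clusters.

    Attributes
    ----------
    labels_ : ndarray of int, 1-based cluster ids
    n_clusters_ : int
    partition_history_ : list of label vectors, one per accepted partition
    ch_scores_ : dict mapping K -> CH score of the accepted K-partition
    """

    def __init__(self, max_share: float = 0.40, k_max: int = 10, n_init: int = 10,
                 max_iter: int = 100, random_state=None):
        self.max_share = max_share
        self.k_max = k_max
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if not (0 < self.max_share < 1):
            raise ValueError(f"max_share must lie in (0, 1), got {self.max_share}")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 pixels to segment")
        rng = check_random_state(self.random_state)
        n = X.shape[0]

        labels = np.ones(n, dtype=int)
        k = 1
        history: list[np.ndarray] = [labels.copy()]
        ch: dict[int, float] = {}

        def largest() -> tuple[int, int]:
            ids, counts = np.unique(labels, return_counts=True)
            j = counts.argmax()
            return int(ids[j]), int(counts[j])

        def bisect(target: int) -> np.ndarray:
            idx = np.flatnonzero(labels == target)
            sub = CorrelationKMeans(
                n_clusters=2, n_init=self.n_init, max_iter=self.max_iter,
                random_state=rng,
            ).fit(X[idx])
            new = labels.copy()
            new[idx[sub.labels_ == 1]] = k + 1
            return new

        # phase 1: mandatory splits until the share rule holds
        while largest()[1] / n > self.max_share:
            if k >= min(self.k_max, n):
                break
            labels = bisect(largest()[0])
            k += 1
            history.append(labels.copy())
            ch[k] = calinski_harabasz(X, labels)

        # phase 2: CH-greedy continuation
        while k < self.k_max:
            candidate = bisect(largest()[0])
            score = calinski_harabasz(X, candidate)
            if ch and score <= ch[k]:
                break
            labels = candidate
            k += 1
            history.append(labels.copy())
            ch[k] = score

        self.labels_ = labels
        self.n_clusters_ = k
        self.partition_history_ = history
        self.ch_scores_ = ch
        return self

    def to_cluster_image(self) -> ClusterImage:
        check_is_fitted(self)
        return ClusterImage(
            labels=self.labels_,
            k=self.n_clusters_,
            partition_history=self.partition_history_,
            ch_scores=self.ch_scores_,
        )


def bisecting_segmentation(
    X, max_share: float = 0.40, k_max: int = 10, seed=None, n_init: int = 10
) -> ClusterImage:
    """Functional wrapper around :class:`BisectingKMeans`."""
    est = BisectingKMeans(
        max_share=max_share, k_max=k_max, n_init=n_init, random_state=seed
    ).fit(X)
    return est.to_cluster_image()


def cluster_composition(labels: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Fraction of each group's pixels falling in each cluster.

    Rows are group labels (e.g. model or treatment), columns cluster ids;
    each row sums to one.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape[0] != groups.shape[0]:
        raise ValueError("labels and groups must align")
    tab = pd.crosstab(pd.Series(groups, name="group"), pd.Series(labels, name="cluster"))
    return tab.div(tab.sum(axis=1), axis=0)
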