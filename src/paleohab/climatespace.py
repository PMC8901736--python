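"""Occupations in temperature-precipitation space.

Buffer-mean temperature and precipitation place each occupation as a point
in a 2-D climate space. This module provides the central-interval summary
("68% of occupations fall within ..."), the scaled Euclidean dissimilarity
between occupations ("equal combinations" of the two variables after
z-scoring), and hierarchical clustering with the optimal number of groups
chosen by the average-silhouette criterion over k-means solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DegenerateScalingError, InvalidConfigError
from .matstats import DistanceMatrix


def central_interval(
    values, coverage: float = 0.6827, mode: str = "normal"
) -> tuple[float, float, int]:
    """Central interval containing ``coverage`` mass, plus the count inside.

    ``normal`` mode returns mean +/- z*sd with z the normal quantile giving
    the requested two-sided coverage (z = 1 at 68.27%); ``quantile`` mode
    returns empirical quantiles at (1 +/- coverage)/2. The sd is the sample
    (n-1) convention. All-equal input yields a zero-width interval that
    contains every value.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise InvalidConfigError("central_interval needs >= 2 values")
    if not 0 < coverage <= 1:
        raise InvalidConfigError("coverage must be in (0, 1]")
    if mode == "normal":
        m = values.mean()
        s = values.std(ddof=1)
        z = norm.ppf(0.5 + coverage / 2.0) if coverage < 1 else np.inf
        if s == 0:
            lo = hi = m
        elif np.isinf(z):
            lo, hi = -np.inf, np.inf
        else:
            lo, hi = m - z * s, m + z * s
    elif mode == "quantile":
        lo = float(np.quantile(values, (1 - coverage) / 2.0))
        hi = float(np.quantile(values, (1 + coverage) / 2.0))
    else:
        raise InvalidConfigError(f"unknown interval mode {mode!r}")
    n_within = int(np.sum((values >= lo) & (values <= hi)))
    return float(lo), float(hi), n_within


def scale_points(points: pd.DataFrame) -> np.ndarray:
    """Z-score temp_mean and precip_mean columns across occupations."""
    X = points[["temp_mean", "precip_mean"]].to_numpy(float)
    if X.shape[0] < 2:
        raise InvalidConfigError("need >= 2 climate points")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(("temp_mean", "precip_mean"), sd) if s == 0]
        raise DegenerateScalingError(f"zero variance in {bad}; cannot scale")
    return (X - X.mean(axis=0)) / sd


def climate_distance(points: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between z-scored (temperature, precipitation) pairs.

    Scaling first gives the two variables equal weight in the combination.
    """
    X = scale_points(points)
    labels = [str(x) for x in points["occ_id"]]
    return DistanceMatrix(labels=labels, values=squareform(pdist(X)), kind="numeric")


@dataclass
class ClusterSolution:
    """Outcome of silhouette-guided k-means plus a dendrogram cut."""

    k: int
    kmeans_labels: np.ndarray  # 1..k
    tree_labels: np.ndarray  # 1..k, from cutting the agglomerative tree
    merge_tree: np.ndarray  # scipy linkage matrix
    silhouette_by_k: dict[int, float]

    @property
    def agreement(self) -> bool:
        """Do the k-means and dendrogram partitions coincide (up to relabelling)?"""
        return _same_partition(self.kmeans_labels, self.tree_labels)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))


def cluster_occupations(
    D: DistanceMatrix,
    X: np.ndarray,
    k_max: int = 10,
    linkage: str = "complete",
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterSolution:
    """Choose k by average silhouette over k-means, cut the tree at that k.

    The silhouette profile is computed for k = 2..k_max k-means solutions
    (``n_restarts`` restarts at a fixed seed); the optimal k is the argmax.
    An agglomerative tree built on ``D`` (configurable linkage) is cut into
    the same number of groups; both label sets are returned so that any
    disagreement between the flat and hierarchical partitions is visible.
    """
    n = X.shape[0]
    if n < 3:
        raise InvalidConfigError("clustering needs >= 3 occupations")
    if not 2 <= k_max < n:
        raise InvalidConfigError("need 2 <= k_max < n")
    if linkage not in ("complete", "average", "ward"):
        raise InvalidConfigError(f"unsupported linkage {linkage!r}")
    if np.allclose(pdist(X), 0):
        raise DegenerateScalingError("all points identical; clustering undefined")

    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, lab))
        labels_by_k[k] = lab + 1
    k_opt = max(sil, key=lambda k: (sil[k], -k))

    if linkage == "ward":
        Z = scipy_linkage(X, method="ward")
    else:
        Z = scipy_linkage(squareform(D.values, checks=False), method=linkage)
    tree_labels = fcluster(Z, t=k_opt, criterion="maxclust")
    return ClusterSolution(
        k=k_opt,
        kmeans_labels=labels_by_k[k_opt],
        tree_labels=tree_labels,
        merge_tree=Z,
        silhouette_by_k=sil,
    )


def cluster_summary(
    points: pd.DataFrame, solution: ClusterSolution, labels: str = "kmeans"
) -> pd.DataFrame:
    """Per-cluster climate ranges (min/max of each variable, member count)."""
    lab = solution.kmeans_labels if labels == "kmeans" else solution.tree_labels
    df = points.copy()
    df["cluster"] = lab
    return (
        df.groupby("cluster")
        .agg(
            n=("occ_id", "size"),
            temp_min=("temp_mean", "min"),
            temp_max=("temp_mean", "max"),
            precip_min=("precip_mean", "min"),
            precip_max=("precip_mean", "max"),
        )
        .reset_index()
    )
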