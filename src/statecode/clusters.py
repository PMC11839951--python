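"""Consensus clustering of single-unit encoding profiles.

Each unit is a five-element vector: cross-validated explained variance
from stimulus, behavior, same-area LFP and other-area population
activity, plus the number of categories exceeding 10% explanatory
power.  Repeated UMAP embeddings with randomized hyperparameters are
mean-shift clustered; the co-association matrix (pairwise co-clustering
frequency) is cut with hierarchical clustering at the silhouette-curve
elbow, and clusters sharing a dominant category with no competing
secondary source are merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import MeanShift, estimate_bandwidth
from sklearn.metrics import silhouette_score

from .states import elbow_point

__all__ = [
    "PROFILE_CATEGORIES",
    "encoding_profile",
    "consensus_coassociation",
    "cut_and_merge",
    "merge_by_dominant_category",
    "ConsensusClustering",
    "ClusterSolution",
]

PROFILE_CATEGORIES = ("stimulus", "behavior", "internal-lfp", "internal-population")


def encoding_profile(category_r2: dict[str, float], threshold: float = 0.10) -> np.ndarray:
    """Five-element encoding profile of one unit.

    ``[r2_stim, r2_behavior, r2_lfp, r2_population, n_categories]`` where
    the count applies a strict ``> threshold`` rule.
    """
    missing = [c for c in PROFILE_CATEGORIES if c not in category_r2]
    if missing:
        raise ValueError(f"missing category cvR^2 entries: {missing}")
    vals = np.array([float(category_r2[c]) for c in PROFILE_CATEGORIES])
    return np.concatenate([vals, [float(np.sum(vals > threshold))]])


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """UMAP + mean-shift consensus clustering with a hierarchical cut.

    Parameters mirror the randomized-consensus workflow: each of
    ``n_repeats`` iterations embeds the (standardized) profiles with
    UMAP under hyperparameters drawn uniformly from
    ``min_dist in [0.02, 0.5]``, ``n_neighbors in [5, 10]``,
    ``n_components in [2, 5]``, then clusters the embedding with
    mean-shift (bandwidth from a random quantile in [0.25, 0.5]).  The
    co-association matrix (fraction of repeats in which two units share
    a cluster) is cut by average-linkage hierarchical clustering; the
    cluster count is the elbow of the silhouette curve over ``k_range``
    (falling back to the silhouette argmax when the curve has no
    elbow).  Clusters whose mean profile has the same dominant category
    and no secondary category above ``merge_threshold`` are merged.

    Attributes
    ----------
    coassociation_ : (n, n) symmetric co-clustering frequencies, unit diagonal.
    labels_, merged_labels_ : cluster labels before/after merging.
    k_, silhouette_curve_, merge_map_ : selection diagnostics.
    """

    def __init__(
        self,
        n_repeats: int = 200,
        k_range: tuple[int, ...] | None = None,
        min_dist_range: tuple[float, float] = (0.02, 0.5),
        n_neighbors_range: tuple[int, int] = (5, 10),
        n_components_range: tuple[int, int] = (2, 5),
        bandwidth_quantile_range: tuple[float, float] = (0.25, 0.5),
        linkage_method: str = "average",
        merge_threshold: float = 0.10,
        random_state: int | None = None,
    ):
        self.n_repeats = n_repeats
        self.k_range = k_range
        self.min_dist_range = min_dist_range
        self.n_neighbors_range = n_neighbors_range
        self.n_components_range = n_components_range
        self.bandwidth_quantile_range = bandwidth_quantile_range
        self.linkage_method = linkage_method
        self.merge_threshold = merge_threshold
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "ConsensusClustering":
        P = np.atleast_2d(np.asarray(X, dtype=float))
        n = P.shape[0]
        if n < 10:
            raise ValueError("need at least 10 units to cluster")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        self.coassociation_ = consensus_coassociation(
            P,
            n_repeats=self.n_repeats,
            min_dist_range=self.min_dist_range,
            n_neighbors_range=self.n_neighbors_range,
            n_components_range=self.n_components_range,
            bandwidth_quantile_range=self.bandwidth_quantile_range,
            seed=self.random_state,
        )
        sol = cut_and_merge(
            self.coassociation_,
            profiles=P,
            k_range=self.k_range,
            linkage_method=self.linkage_method,
            merge_threshold=self.merge_threshold,
        )
        self.labels_ = sol.labels
        self.merged_labels_ = sol.merged_labels
        self.k_ = sol.k
        self.silhouette_curve_ = sol.silhouette_curve
        self.merge_map_ = sol.merge_map
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).merged_labels_


def consensus_coassociation(
    profiles: np.ndarray,
    n_repeats: int = 200,
    min_dist_range: tuple[float, float] = (0.02, 0.5),
    n_neighbors_range: tuple[int, int] = (5, 10),
    n_components_range: tuple[int, int] = (2, 5),
    bandwidth_quantile_range: tuple[float, float] = (0.25, 0.5),
    seed: int | None = None,
) -> np.ndarray:
    """Co-association matrix over randomized UMAP + mean-shift repeats.

    A repeat that assigns all units to a single cluster is a valid
    outcome and is counted.  Deterministic under a fixed ``seed``.
    """
    import umap  # heavy import deferred to first use

    P = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = P.shape[0]
    if n < 10:
        raise ValueError("need at least 10 units")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    sd = P.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (P - P.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    single_cluster_repeats = 0
    for _ in range(n_repeats):
        md = rng.uniform(*min_dist_range)
        nn = int(rng.integers(n_neighbors_range[0], n_neighbors_range[1] + 1))
        nc = int(rng.integers(n_components_range[0], n_components_range[1] + 1))
        nn = min(nn, n - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = umap.UMAP(
                n_neighbors=nn,
                min_dist=md,
                n_components=nc,
                random_state=int(rng.integers(2**31)),
            ).fit_transform(Z)
        q = rng.uniform(*bandwidth_quantile_range)
        bw = estimate_bandwidth(emb, quantile=q)
        if not np.isfinite(bw) or bw <= 0:
            bw = None
        labels = MeanShift(bandwidth=bw).fit_predict(emb)
        if np.unique(labels).size == 1:
            single_cluster_repeats += 1
        co += labels[:, None] == labels[None, :]
    if single_cluster_repeats:
        warnings.warn(
            f"{single_cluster_repeats}/{n_repeats} repeats collapsed to one cluster",
            RuntimeWarning,
        )
    co /= n_repeats
    np.fill_diagonal(co, 1.0)
    return co


@dataclass
class ClusterSolution:
    """Hierarchical cut of a co-association matrix plus merged labels."""

    labels: np.ndarray
    k: int
    silhouette_curve: np.ndarray
    k_range: tuple[int, ...]
    merged_labels: np.ndarray
    merge_map: dict[int, int]


def cut_and_merge(
    coassoc: np.ndarray,
    profiles: np.ndarray,
    k_range: tuple[int, ...] | None = None,
    linkage_method: str = "average",
    merge_threshold: float = 0.10,
) -> ClusterSolution:
    """Cut the co-association matrix and merge same-dominant clusters.

    The distance is ``1 - coassociation``; hierarchical clustering is
    cut at every k in ``k_range`` and the silhouette score (precomputed
    distance) is recorded; k* is the curve's elbow, or its argmax when
    no elbow exists (logged).  Merging applies the dominant-category
    rule on the mean raw profiles.
    """
    co = np.asarray(coassoc, dtype=float)
    n = co.shape[0]
    if k_range is None:
        k_range = tuple(range(2, min(11, n)))
    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    sil = []
    labelings = {}
    for k in k_range:
        lab = fcluster(Z, t=k, criterion="maxclust") - 1
        labelings[k] = lab
        if np.unique(lab).size < 2:
            sil.append(-1.0)
        else:
            sil.append(float(silhouette_score(dist, lab, metric="precomputed")))
    sil = np.asarray(sil)
    e = elbow_point(sil) if sil.size >= 3 else None
    if e is None:
        warnings.warn("silhouette curve has no elbow; using its argmax", RuntimeWarning)
        k_star = int(k_range[int(np.argmax(sil))])
    else:
        k_star = int(k_range[e])
    labels = labelings[k_star]
    merged, merge_map = merge_by_dominant_category(labels, profiles, merge_threshold)
    return ClusterSolution(labels, k_star, sil, tuple(k_range), merged, merge_map)


def merge_by_dominant_category(
    labels: np.ndarray, profiles: np.ndarray, threshold: float = 0.10
) -> tuple[np.ndarray, dict[int, int]]:
    """Merge clusters dominated by the same single source category.

    A cluster is mergeable when its mean profile's second-largest
    category entry (over the four cvR^2 entries) stays below
    ``threshold``; mergeable clusters sharing the argmax category
    collapse into one.  Clusters with a competing secondary source are
    left untouched.  Merging never increases the cluster count.
    """
    labels = np.asarray(labels, dtype=int)
    P = np.atleast_2d(np.asarray(profiles, dtype=float))[:, :4]
    uniq = np.unique(labels)
    dominant, mergeable = {}, {}
    for c in uniq:
        mean_p = P[labels == c].mean(axis=0)
        order = np.argsort(mean_p)[::-1]
        dominant[c] = int(order[0])
        mergeable[c] = bool(mean_p[order[1]] < threshold)
    merge_map: dict[int, int] = {}
    groups: dict[int, int] = {}
    next_id = 0
    for c in uniq:
        if mergeable[c]:
            key = dominant[c]
            if key not in groups:
                groups[key] = next_id
                next_id += 1
            merge_map[int(c)] = groups[key]
        else:
            merge_map[int(c)] = next_id
            next_id += 1
    merged = np.array([merge_map[int(c)] for c in labels])
    return merged, merge_map
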