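"""The eight feature-selection strategies and cross-dataset consensus.

Four strategies were designed as presumptively poor selectors — lowest
information gain (LIG), random features (RFS), a random member per feature
cluster (RFC), and representatives of the largest clusters (SFC) — and four
as presumptively good ones: highest information gain (HIG), the highest-IG
member per cluster (HIC), zero-norm selection over positive-class values
(ZNF), and a Pearson-correlation redundancy filter (PCF).  A consensus
(COMBINED) selection ranks features by how often they occur among several
per-dataset top lists.

Information gain is computed in bits on equal-width discretized features.
Feature clustering runs k-means over features embedded as z-scored vectors
of their per-sample values.  Every tie anywhere is broken by ascending
feature name, so all selectors are deterministic given their inputs and
seed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .table import POSITIVE, FeatureTable
from .tablio import SelectionResult


class SelectionError(ValueError):
    """Raised when a selector's preconditions are not met."""


@dataclass(frozen=True)
class FSConfig:
    """Shared feature-selection parameters.

    ``m`` is the selection size handed to model training (default 50, small
    enough that feature-set differences are not concealed by incidental good
    features).  ``k_clusters`` is the feature-cluster count behind RFC, SFC
    and HIC (default 100).  ``n_bins`` controls equal-width discretization
    for information gain.  ``top_for_combined`` is the per-dataset list
    length pooled by the consensus selection.
    """

    m: int = 50
    k_clusters: int = 100
    n_bins: int = 10
    top_for_combined: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise SelectionError(f"m must be >= 1, got {self.m}")
        if self.k_clusters < 1:
            raise SelectionError(f"k_clusters must be >= 1, got {self.k_clusters}")
        if self.n_bins < 2:
            raise SelectionError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.top_for_combined < self.m:
            raise SelectionError("top_for_combined must be >= m")


# ---------------------------------------------------------------------------
# information gain


def discretize_equal_width(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Map reals to equal-width bin indices over their observed range.

    Bin ``i`` covers ``[min + i*w, min + (i+1)*w)`` with ``w = range/n_bins``;
    the last bin is closed.  A constant column maps entirely to bin 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise SelectionError("cannot discretize an empty column")
    if n_bins < 2:
        raise SelectionError(f"n_bins must be >= 2, got {n_bins}")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=int)
    w = (hi - lo) / n_bins
    bins = np.floor((values - lo) / w).astype(int)
    return np.clip(bins, 0, n_bins - 1)


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(bins: np.ndarray, labels: np.ndarray) -> float:
    """Information gain of a discrete feature about the labels, in bits.

    ``IG = H(Y) - sum_v P(X=v) H(Y | X=v)``, log base 2; always within
    ``[0, H(Y)]``.
    """
    bins = np.asarray(bins)
    labels = np.asarray(labels)
    if len(bins) != len(labels):
        raise SelectionError(
            f"length mismatch: {len(bins)} bins vs {len(labels)} labels"
        )
    if len(bins) == 0:
        raise SelectionError("empty input")
    n = len(labels)
    h_y = _entropy_bits(labels)
    h_cond = 0.0
    for v in np.unique(bins):
        mask = bins == v
        h_cond += (mask.sum() / n) * _entropy_bits(labels[mask])
    ig = h_y - h_cond
    # clamp tiny negative float residue
    return float(max(ig, 0.0))


def rank_by_ig(table: FeatureTable, cfg: FSConfig) -> list[tuple[str, float]]:
    """All features ordered by IG descending, ties by ascending name."""
    classes = set(table.labels)
    if len(classes) < 2:
        raise SelectionError("information-gain ranking requires both classes")
    scores = []
    for j, name in enumerate(table.feature_names):
        bins = discretize_equal_width(table.values[:, j], cfg.n_bins)
        scores.append((name, information_gain(bins, table.labels)))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# IG-based selectors


def select_hig(table: FeatureTable, cfg: FSConfig, dataset_id: str = "") -> SelectionResult:
    """Top-m features by information gain."""
    ranked = rank_by_ig(table, cfg)[: cfg.m]
    return SelectionResult(
        "HIG", dataset_id or table.provenance,
        [f for f, _ in ranked], [s for _, s in ranked], m=len(ranked),
    )


def select_lig(table: FeatureTable, cfg: FSConfig, dataset_id: str = "") -> SelectionResult:
    """Bottom-m features by information gain (lowest IG first)."""
    ranked = sorted(rank_by_ig(table, cfg), key=lambda t: (t[1], t[0]))[: cfg.m]
    return SelectionResult(
        "LIG", dataset_id or table.provenance,
        [f for f, _ in ranked], [s for _, s in ranked], m=len(ranked),
    )


def select_rfs(table: FeatureTable, cfg: FSConfig, dataset_id: str = "") -> SelectionResult:
    """m features drawn uniformly without replacement (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    m = min(cfg.m, table.n_features)
    picked = rng.choice(table.n_features, size=m, replace=False)
    feats = [table.feature_names[i] for i in picked]
    return SelectionResult("RFS", dataset_id or table.provenance, feats, m=m)


# ---------------------------------------------------------------------------
# feature clustering


@dataclass
class FeatureClustering:
    """k-means partition of features embedded in standardized sample space.

    ``labels[i]`` is the 0-based cluster of ``feature_names[i]``;
    ``centroid_dist[i]`` its Euclidean distance to that cluster's centroid.
    Empty clusters are retained with size 0.
    """

    feature_names: list[str]
    labels: np.ndarray
    centroids: np.ndarray
    centroid_dist: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.sizes = np.bincount(self.labels, minlength=self.k)
        if self.sizes.sum() != len(self.feature_names):
            raise SelectionError("cluster assignment is not a partition")

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.feature_names, (int(c) for c in self.labels)))

    def members(self, cluster: int) -> list[str]:
        return sorted(
            self.feature_names[i] for i in np.flatnonzero(self.labels == cluster)
        )

    def members_by_centrality(self, cluster: int) -> list[str]:
        """Cluster members closest-to-centroid first, ties by name."""
        idx = np.flatnonzero(self.labels == cluster)
        order = sorted(idx, key=lambda i: (self.centroid_dist[i], self.feature_names[i]))
        return [self.feature_names[i] for i in order]


def cluster_features(table: FeatureTable, cfg: FSConfig) -> FeatureClustering:
    """k-means over features as z-scored per-sample vectors.

    Each feature is standardized across samples (constant features become
    zero vectors) and treated as a point in R^n_samples; k-means runs with
    seeded initialization and 10 restarts, keeping the lowest within-cluster
    sum of squares.
    """
    p = table.n_features
    if p < cfg.k_clusters:
        raise SelectionError(
            f"p={p} features but k_clusters={cfg.k_clusters}; lower k_clusters"
        )
    X = table.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    points = ((X - mu) / sd).T  # p x n_samples
    km = KMeans(
        n_clusters=cfg.k_clusters,
        n_init=10,
        random_state=cfg.seed % (2**32),
        algorithm="lloyd",
    ).fit(points)
    dist = np.linalg.norm(points - km.cluster_centers_[km.labels_], axis=1)
    return FeatureClustering(
        feature_names=list(table.feature_names),
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        centroid_dist=dist,
        k=cfg.k_clusters,
    )


def _nonempty_clusters(clustering: FeatureClustering) -> list[int]:
    return [c for c in range(clustering.k) if clustering.sizes[c] > 0]


def select_rfc(
    clustering: FeatureClustering, cfg: FSConfig, dataset_id: str = ""
) -> SelectionResult:
    """One random member per cluster, then m chosen at random among those."""
    rng = np.random.default_rng(cfg.seed)
    reps = []
    for c in _nonempty_clusters(clustering):
        members = clustering.members(c)
        reps.append(members[rng.integers(len(members))])
    perm = rng.permutation(len(reps))
    feats = [reps[i] for i in perm[: cfg.m]]
    return SelectionResult("RFC", dataset_id, feats, m=len(feats))


def select_sfc(
    clustering: FeatureClustering, cfg: FSConfig, dataset_id: str = ""
) -> SelectionResult:
    """Centroid-closest representatives of the largest clusters.

    Clusters are ordered by size descending (ties by their lexicographically
    smallest member); pass 1 takes each cluster's centroid-closest member in
    that order, pass 2 each cluster's next-closest, and so on until m
    features are collected.
    """
    order = sorted(
        _nonempty_clusters(clustering),
        key=lambda c: (-int(clustering.sizes[c]), clustering.members(c)[0]),
    )
    ranked_members = {c: clustering.members_by_centrality(c) for c in order}
    feats: list[str] = []
    rank = 0
    while len(feats) < cfg.m:
        took = False
        for c in order:
            if len(feats) >= cfg.m:
                break
            members = ranked_members[c]
            if rank < len(members):
                feats.append(members[rank])
                took = True
        if not took:  # all features exhausted
            break
        rank += 1
    return SelectionResult("SFC", dataset_id, feats, m=len(feats))


def select_hic(
    table: FeatureTable,
    clustering: FeatureClustering,
    cfg: FSConfig,
    dataset_id: str = "",
) -> SelectionResult:
    """Highest-IG member per cluster, re-ranked by IG, top m."""
    if set(table.feature_names) != set(clustering.feature_names):
        raise SelectionError("table and clustering cover different features")
    ig = dict(rank_by_ig(table, cfg))
    reps: list[tuple[str, float]] = []
    for c in _nonempty_clusters(clustering):
        members = clustering.members(c)
        best = min(members, key=lambda f: (-ig[f], f))
        reps.append((best, ig[best]))
    reps.sort(key=lambda t: (-t[1], t[0]))
    reps = reps[: cfg.m]
    return SelectionResult(
        "HIC", dataset_id or table.provenance,
        [f for f, _ in reps], [s for _, s in reps], m=len(reps),
    )


# ---------------------------------------------------------------------------
# value-based selectors


def select_znf(table: FeatureTable, cfg: FSConfig, dataset_id: str = "") -> SelectionResult:
    """Zero-norm selection on positive-class values.

    Candidates are features with no exactly-zero entry among positive
    samples; they are ranked by the sum of their values over positives,
    descending.  Negative rows never influence the result.
    """
    pos = table.values[table.label_mask(POSITIVE)]
    if pos.shape[0] == 0:
        raise SelectionError("ZNF requires at least one positive sample")
    nonzero = ~np.any(pos == 0.0, axis=0)
    sums = pos.sum(axis=0)
    cand = [
        (table.feature_names[j], float(sums[j]))
        for j in np.flatnonzero(nonzero)
    ]
    cand.sort(key=lambda t: (-t[1], t[0]))
    cand = cand[: cfg.m]
    return SelectionResult(
        "ZNF", dataset_id or table.provenance,
        [f for f, _ in cand], [s for _, s in cand], m=len(cand),
    )


def select_pcf(table: FeatureTable, cfg: FSConfig, dataset_id: str = "") -> SelectionResult:
    """Pearson redundancy filter: keep the least-correlated features.

    Each feature's redundancy score is its mean absolute Pearson correlation
    against all other features (pairs involving a constant feature count as
    0); the m lowest-scoring features are kept, lowest first.
    """
    p = table.n_features
    if p < 2:
        raise SelectionError("PCF requires at least two features")
    X = table.values
    sd = X.std(axis=0)
    variable = sd > 0
    scores = np.zeros(p)
    if variable.sum() >= 2:
        corr = np.corrcoef(X[:, variable].T)
        np.fill_diagonal(corr, 0.0)
        scores[variable] = np.abs(corr).sum(axis=1) / (p - 1)
    pairs = sorted(
        zip(table.feature_names, scores.tolist()), key=lambda t: (t[1], t[0])
    )[: cfg.m]
    return SelectionResult(
        "PCF", dataset_id or table.provenance,
        [f for f, _ in pairs], [s for _, s in pairs], m=len(pairs),
    )


# ---------------------------------------------------------------------------
# consensus


def combine_selections(
    per_dataset_rankings: list[list[str]],
    cfg: FSConfig,
    dataset_id: str = "combined",
    method: str = "COMBINED",
) -> SelectionResult:
    """Consensus selection by occurrence frequency across dataset rankings.

    Each feature's frequency is the number of rankings containing it;
    ordering is frequency descending, ties by mean rank across the rankings
    containing the feature (ascending), then by name.
    """
    if not per_dataset_rankings:
        raise SelectionError("no rankings to combine")
    freq: dict[str, int] = defaultdict(int)
    ranksum: dict[str, int] = defaultdict(int)
    for ranking in per_dataset_rankings:
        if len(set(ranking)) != len(ranking):
            raise SelectionError("a ranking contains duplicate features")
        for pos_idx, f in enumerate(ranking, start=1):
            freq[f] += 1
            ranksum[f] += pos_idx
    ordered = sorted(
        freq, key=lambda f: (-freq[f], ranksum[f] / freq[f], f)
    )[: cfg.m]
    return SelectionResult(
        method, dataset_id, ordered, [float(freq[f]) for f in ordered], m=len(ordered)
    )
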