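"""Clustering of compatible fits in parameter space.

Parameters are z-scored (sample standard deviation), the number of clusters
is chosen by majority vote over five internal validity indices for
k = 2..10, fits are grouped by seeded k-means, and the first three principal
components are exported for visualization.  Distinct clusters typically
expose alternative regulatory logics — different sets of highly active
sites producing the same expression pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "ClusterAssignment",
    "z_transform",
    "choose_k",
    "kmeans_cluster",
    "pca_project",
    "cluster_fits",
    "per_cluster_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterAssignment:
    """Labels, chosen k, per-index votes and PCA coordinates for an ensemble."""

    labels: np.ndarray           # 1-based, canonical (clusters sorted by size)
    chosen_k: int
    votes: dict[str, int]
    pca_coords: np.ndarray       # (n_fits, 3)
    explained_variance: np.ndarray
    low_confidence: bool = False


def z_transform(matrix: np.ndarray, return_dropped: bool = False):
    """Standardize columns to mean 0, sd 1 (sample sd, n-1 denominator).

    Constant columns cannot be scaled and are dropped with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a fits x parameters matrix")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant parameter column(s)",
                       int((~keep).sum()))
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if return_dropped:
        return Z, np.flatnonzero(~keep)
    return Z


def _dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance / max intra-cluster diameter."""
    uniq = np.unique(labels)
    diam = 0.0
    for u in uniq:
        pts = X[labels == u]
        if len(pts) > 1:
            diam = max(diam, float(pdist(pts).max()))
    if diam == 0.0:
        return np.inf
    sep = np.inf
    for i, u in enumerate(uniq):
        for v in uniq[i + 1:]:
            sep = min(sep, float(cdist(X[labels == u], X[labels == v]).min()))
    return sep / diam


def _gap_statistic(X: np.ndarray, k: int, seed: int, n_ref: int = 10) -> float:
    """Gap statistic against uniform reference data in the bounding box."""
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    log_w = np.log(max(km.inertia_, 1e-300))
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = []
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_logs.append(
            np.log(max(KMeans(n_clusters=k, n_init=3,
                              random_state=seed).fit(ref).inertia_, 1e-300))
        )
    return float(np.mean(ref_logs) - log_w)


def choose_k(Z: np.ndarray, k_range: Sequence[int] = range(2, 11),
             seed: int = 0) -> tuple[int, dict[str, int], bool]:
    """Majority vote over 5 validity indices (silhouette, Calinski–Harabasz,
    Davies–Bouldin, gap statistic, Dunn); ties go to the smaller k.

    Returns (best_k, votes per index, low_confidence).  ``low_confidence``
    is set when no k obtains more than one vote (structureless data); the
    reported k then falls back to the smallest candidate.
    """
    ks = [k for k in k_range if k < len(Z)]
    if not ks:
        raise ValueError("not enough fits to cluster")
    scores: dict[str, dict[int, float]] = {
        "silhouette": {}, "calinski_harabasz": {}, "davies_bouldin": {},
        "gap": {}, "dunn": {},
    }
    for k in ks:
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(Z)
        if len(np.unique(labels)) < 2:
            continue
        scores["silhouette"][k] = silhouette_score(Z, labels)
        scores["calinski_harabasz"][k] = calinski_harabasz_score(Z, labels)
        scores["davies_bouldin"][k] = -davies_bouldin_score(Z, labels)  # lower is better
        scores["gap"][k] = _gap_statistic(Z, k, seed)
        scores["dunn"][k] = _dunn_index(Z, labels)
    votes = {}
    for index, by_k in scores.items():
        if by_k:
            votes[index] = min(
                (k for k in by_k
                 if by_k[k] >= max(by_k.values()) - 1e-12),
            )
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    top = max(tally.values())
    low_confidence = top <= 1
    if low_confidence:
        best = min(ks)
    else:
        best = min(k for k, c in tally.items() if c == top)
    return best, votes, low_confidence


def kmeans_cluster(Z: np.ndarray, k: int, seed: int = 0,
                   n_init: int = 10) -> np.ndarray:
    """Seeded k-means returning canonical 1-based labels.

    Clusters are renumbered by size, descending (ties by first occurrence),
    so the labelling is invariant to k-means' internal label permutation.
    """
    if k == 1:
        return np.ones(len(Z), dtype=int)
    raw = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit_predict(Z)
    sizes = {lab: int((raw == lab).sum()) for lab in np.unique(raw)}
    first = {lab: int(np.argmax(raw == lab)) for lab in sizes}
    order = sorted(sizes, key=lambda lab: (-sizes[lab], first[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw], dtype=int)


def pca_project(Z: np.ndarray, n_components: int = 3
                ) -> tuple[np.ndarray, np.ndarray]:
    """PCA via covariance eigendecomposition.

    Components are ordered by explained variance with the sign convention
    that each component's largest-magnitude loading is positive.  Returns
    (coords (n, c), explained variance fractions (c,)).
    """
    X = np.asarray(Z, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    c = min(n_components, X.shape[1])
    W = evecs[:, :c]
    for j in range(c):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    total = evals.sum()
    frac = evals[:c] / total if total > 0 else np.zeros(c)
    return Xc @ W, frac


def cluster_fits(param_matrix: np.ndarray, seed: int = 0,
                 k: int | None = None,
                 k_range: Sequence[int] = range(2, 11)) -> ClusterAssignment:
    """z-transform, choose k (unless given), k-means, and PCA in one call."""
    Z = z_transform(param_matrix)
    low_conf = False
    votes: dict[str, int] = {}
    if k is None:
        k, votes, low_conf = choose_k(Z, k_range, seed)
    labels = kmeans_cluster(Z, k, seed)
    coords, ev = pca_project(Z)
    return ClusterAssignment(labels=labels, chosen_k=k, votes=votes,
                             pca_coords=coords, explained_variance=ev,
                             low_confidence=low_conf)


def per_cluster_analysis(fits, labels: np.ndarray, model, profiles, nu: float,
                         fraction: float = 0.8, layer: str = "RT") -> dict:
    """Ensemble site summaries and functional clusters per fit-cluster label.

    Smaller clusters are reported alongside the dominant one rather than
    discarded: an alternative-logic cluster is still a candidate hypothesis.
    """
    from .ensemble_analysis import (
        identify_functional_clusters,
        weighted_site_frequency,
    )

    out = {}
    for label in sorted(set(int(l) for l in labels)):
        members = [f for f, l in zip(fits, labels) if int(l) == label]
        summary = weighted_site_frequency(members, model, profiles, nu,
                                          fraction, layer)
        best = min(members, key=lambda f: f.rms)
        fclusters = identify_functional_clusters(best, model, profiles, nu,
                                                 fraction=fraction, layer=layer)
        out[label] = {
            "n_fits": len(members),
            "site_summary": summary,
            "functional_clusters": fclusters,
        }
    return out
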