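"""Hierarchical clustering on principal components.

Ward agglomeration on component scores, cluster-count selection by the
relative loss of within-cluster inertia, and k-means (Lloyd) consolidation
initialised at the hierarchical centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterSolution",
    "ward_tree",
    "cut_tree",
    "choose_q",
    "consolidate",
    "hcpc",
    "within_inertia",
    "total_inertia",
]


@dataclass
class Dendrogram:
    """Ward merge tree with per-merge within-inertia increases."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4 format; column 2 = Ward heights
    n: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def gains(self) -> np.ndarray:
        """Within-inertia increase of each merge (Ward height squared over 2)."""
        return self.heights**2 / 2.0

    def within_inertia_at(self, q: int) -> float:
        """Sum of within-cluster inertia of the q-cluster cut."""
        if not 1 <= q <= self.n:
            raise ValueError(f"q must be in 1..{self.n}")
        return float(self.gains[: self.n - q].sum())


@dataclass
class ClusterSolution:
    labels: np.ndarray        # 1..q
    q: int
    within: float             # within-cluster inertia after consolidation
    n_iter: int
    centroids: np.ndarray
    history: list[str] = field(default_factory=list)


def total_inertia(scores: np.ndarray) -> float:
    scores = np.asarray(scores, dtype=float)
    return float(((scores - scores.mean(axis=0)) ** 2).sum())


def within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    w = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(w)


def ward_tree(scores: np.ndarray) -> Dendrogram:
    """Ward (minimum within-inertia increase) agglomeration on Euclidean scores."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    Z = linkage(scores, method="ward")
    return Dendrogram(linkage_matrix=Z, n=scores.shape[0])


def cut_tree(tree: Dendrogram, q: int) -> np.ndarray:
    """Labels 1..q for the q-cluster cut, renumbered by decreasing cluster size."""
    raw = fcluster(tree.linkage_matrix, t=q, criterion="maxclust")
    sizes = {lab: int((raw == lab).sum()) for lab in np.unique(raw)}
    order = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw], dtype=int)


def choose_q(tree: Dendrogram, q_max: int = 10) -> int:
    """Cluster count by highest relative loss of within-cluster inertia.

    With W(q) the within-inertia of the q-cluster cut and
    gain(q) = W(q-1) - W(q), returns the q in 2..q_max maximising
    gain(q)/gain(q+1); ties resolve toward smaller q.
    """
    if q_max < 2:
        raise ValueError("q_max must be >= 2")
    if tree.n <= q_max:
        raise ValueError(f"need n > q_max (n={tree.n}, q_max={q_max})")
    gains = tree.gains
    if gains.sum() <= 0:
        raise ValueError("degenerate data: zero total inertia")
    best_q, best_ratio = None, -np.inf
    for q in range(2, q_max + 1):
        g_q = gains[tree.n - q]       # merge taking q clusters to q-1
        g_next = gains[tree.n - q - 1]
        ratio = np.inf if g_next == 0 else g_q / g_next
        # relative tolerance so numerically tied ratios resolve toward smaller q
        if best_q is None or ratio > best_ratio * (1 + 1e-9) + 1e-12:
            best_q, best_ratio = q, ratio
    return int(best_q)


def consolidate(scores: np.ndarray, initial_labels: np.ndarray, max_iter: int = 100) -> ClusterSolution:
    """Lloyd k-means initialised at the hierarchical cluster centroids."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(initial_labels, dtype=int)
    uniq = np.unique(labels)
    q = len(uniq)
    centroids = np.vstack([scores[labels == lab].mean(axis=0) for lab in uniq])
    lab_of = {i: lab for i, lab in enumerate(uniq)}
    history: list[str] = []

    current = labels.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for ci in range(q):
            if not (assign == ci).any():
                # re-seed an empty cluster with the farthest point from its assigned centroid
                far = int(d2[np.arange(len(scores)), assign].argmax())
                assign[far] = ci
                msg = f"iteration {n_iter}: empty cluster {lab_of[ci]} re-seeded with row {far}"
                history.append(msg)
                logger.warning(msg)
        new_labels = np.array([lab_of[a] for a in assign], dtype=int)
        centroids = np.vstack([scores[new_labels == lab_of[ci]].mean(axis=0) for ci in range(q)])
        if np.array_equal(new_labels, current):
            current = new_labels
            break
        current = new_labels
    return ClusterSolution(
        labels=current,
        q=q,
        within=within_inertia(scores, current),
        n_iter=n_iter,
        centroids=centroids,
        history=history,
    )


def hcpc(scores: np.ndarray, q: int | None = None, q_max: int = 10) -> ClusterSolution:
    """Full pipeline: Ward tree -> cluster-count choice -> k-means consolidation."""
    tree = ward_tree(scores)
    if q is None:
        q = choose_q(tree, q_max=min(q_max, tree.n - 1))
    initial = cut_tree(tree, q)
    solution = consolidate(scores, initial)
    if solution.within > within_inertia(scores, initial) + 1e-9:
        raise AssertionError("consolidation increased within-cluster inertia")
    return solution


def order_fit_frail(labels: np.ndarray, fi: np.ndarray) -> np.ndarray:
    """Renumber a two-cluster solution so cluster 1 = lower-FI ("fit") group.

    Returns labels in {1, 2} with 2 = "frail" (higher mean FI).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("fit/frail ordering requires exactly 2 clusters")
    fi = np.asarray(fi, dtype=float)
    means = {lab: np.nanmean(fi[labels == lab]) for lab in uniq}
    fit_lab = min(uniq, key=lambda lab: means[lab])
    return np.where(labels == fit_lab, 1, 2)
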