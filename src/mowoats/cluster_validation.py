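"""Cluster validity indices and best-solution selection from the elite list.

The optimizer returns a whole Pareto front; a single clustering is picked
by the full Silhouette index: for every archived solution the data are hard-
assigned to its nearest centroid, the Silhouette S(C) of that labeling is
computed, and the solution with the highest S(C) wins.  The report also
carries the Davies-Bouldin index (lower better), the Dunn index (higher
better) and, when generating labels are known, the class-weighted F-measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateSolutionError,
    DomainError,
    SelectionError,
    ShapeError,
)
from .expression_io import ExpressionMatrix
from .objectives import Solution, assign_points
from .pareto_archive import EliteList
from .similarity import pairwise_distances

__all__ = [
    "ClusteringResult",
    "silhouette_full",
    "davies_bouldin",
    "dunn_index",
    "f_measure",
    "select_best_solution",
]

logger = logging.getLogger("mowoats")


@dataclass
class ClusteringResult:
    """Chosen solution, its hard labels, and the validation report."""

    solution: Solution
    labels: np.ndarray
    report: dict[str, float]


def _as_values(data) -> np.ndarray:
    if isinstance(data, ExpressionMatrix):
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=float))


def _point_distances(values: np.ndarray, metric: str) -> np.ndarray:
    return pairwise_distances(values, values, metric)


def silhouette_full(data, labels, metric: str = "euclidean") -> float:
    """Mean Silhouette s(i) = (b_i - a_i) / max(a_i, b_i) over all points.

    a_i is the mean distance to the other members of i's cluster (a
    singleton cluster scores 0); b_i is the smallest mean distance to the
    points of any other cluster.
    """
    values = _as_values(data)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ShapeError("labels length must match point count")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DomainError("Silhouette needs >= 2 non-empty clusters")
    D = _point_distances(values, metric)
    n = values.shape[0]
    s = np.zeros(n)
    # per-cluster summed distances: (n, n_clusters)
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    for i in range(n):
        own = np.searchsorted(uniq, labels[i])
        if sizes[own] == 1:
            continue  # singleton: s(i) = 0
        a = sums[i, own] / (sizes[own] - 1)
        other = np.delete(sums[i] / sizes, own)
        b = other.min()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(s.mean())


def davies_bouldin(
    data,
    labels,
    centroids: np.ndarray | None = None,
    metric: str = "euclidean",
) -> float:
    """Davies-Bouldin index (1/m) sum_i max_{j!=i} (S_i + S_j) / M_ij.

    S_k is the mean distance of cluster-k points to its centroid and M_ij
    the centroid-centroid distance.  By default the scatter is measured
    against the supplied centroids (the optimized representation); pass
    ``centroids=None`` to recompute them as cluster means.
    """
    values = _as_values(data)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DomainError("Davies-Bouldin needs >= 2 clusters")
    if centroids is None:
        centroids = np.stack([values[labels == c].mean(axis=0) for c in uniq])
    else:
        centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
        # keep only centroids of non-empty clusters, in label order
        centroids = centroids[uniq.astype(int)]
    D = pairwise_distances(values, centroids, metric)
    scatter = np.array(
        [D[labels == c, j].mean() for j, c in enumerate(uniq)]
    )
    M = pairwise_distances(centroids, centroids, metric)
    m = uniq.size
    if np.min(M[~np.eye(m, dtype=bool)]) == 0.0:
        raise DegenerateSolutionError("coincident centroids: DBI undefined")
    ratios = (scatter[:, None] + scatter[None, :]) / np.where(M > 0, M, np.inf)
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


def dunn_index(data, labels, metric: str = "euclidean") -> float:
    """Dunn index: min between-cluster single-linkage distance over max
    within-cluster diameter."""
    values = _as_values(data)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DomainError("Dunn index needs >= 2 clusters")
    D = _point_distances(values, metric)
    masks = [labels == c for c in uniq]
    diameters = [D[np.ix_(m, m)].max() for m in masks]
    max_diam = max(diameters)
    if max_diam == 0.0:
        raise DegenerateSolutionError("all clusters singleton/zero-diameter")
    min_sep = min(
        D[np.ix_(masks[i], masks[j])].min()
        for i in range(len(uniq))
        for j in range(i + 1, len(uniq))
    )
    return float(min_sep / max_diam)


def f_measure(labels_pred, labels_true) -> float:
    """Class-size-weighted best-match F-measure between clusters and classes.

    F = sum_i (n_i / n) * max_j F(i, j) with F(i, j) the harmonic mean of
    precision n_ij / n_j and recall n_ij / n_i over the contingency table.
    Invariant to any relabeling of the predicted cluster ids.
    """
    pred = np.asarray(labels_pred)
    true = np.asarray(labels_true)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ShapeError("label vectors must share length")
    n = pred.size
    classes, true_idx = np.unique(true, return_inverse=True)
    clusters, pred_idx = np.unique(pred, return_inverse=True)
    nij = np.zeros((classes.size, clusters.size))
    np.add.at(nij, (true_idx, pred_idx), 1)
    ni = nij.sum(axis=1, keepdims=True)  # class sizes
    nj = nij.sum(axis=0, keepdims=True)  # cluster sizes
    with np.errstate(invalid="ignore", divide="ignore"):
        r = nij / ni
        p = nij / nj
        f = np.where(nij > 0, 2 * p * r / np.where(nij > 0, p + r, 1.0), 0.0)
    return float((ni.ravel() / n * f.max(axis=1)).sum())


def labels_from_solution(data, solution: Solution, metric: str = "euclidean"):
    """Hard labels by nearest-centroid assignment of the solution."""
    return assign_points(data, solution.centroids, metric).i_min


def select_best_solution(
    el: EliteList,
    data,
    metric: str = "euclidean",
    labels_true=None,
) -> ClusteringResult:
    """Pick the elite-list member whose labeling maximizes the full Silhouette.

    Members whose assignment collapses to a single non-empty cluster are
    skipped with a warning; ties go to the earlier member.  The attached
    report carries silhouette, dbi, dunn and (if true labels are given)
    f_measure.
    """
    if len(el) == 0:
        raise SelectionError("elite list is empty")
    values = _as_values(data)
    best: tuple[float, Solution, np.ndarray] | None = None
    for member in el:
        labels = labels_from_solution(values, member, metric)
        if np.unique(labels).size < 2:
            logger.warning("skipping elite solution with a single non-empty cluster")
            continue
        s = silhouette_full(values, labels, metric)
        if best is None or s > best[0]:
            best = (s, member, labels)
    if best is None:
        raise SelectionError("every elite solution collapsed to one cluster")
    s, member, labels = best
    report: dict[str, float] = {"silhouette": s}
    try:
        report["dbi"] = davies_bouldin(values, labels, member.centroids, metric)
    except DegenerateSolutionError:
        report["dbi"] = float("nan")
    try:
        report["dunn"] = dunn_index(values, labels, metric)
    except DegenerateSolutionError:
        report["dunn"] = float("nan")
    if labels_true is not None:
        report["f_measure"] = f_measure(labels, labels_true)
    return ClusteringResult(solution=member, labels=labels, report=report)
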