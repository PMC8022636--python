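"""Rank preprocessing, Spearman coefficient, and the point-to-centroid distance.

Expression profiles from different platforms or species are hard to compare
on raw magnitudes, so similarity can instead be measured on within-profile
ranks: each gene's values are replaced by minimum-order ranks (ties all take
the smallest rank among the tied positions) and the Spearman coefficient

    r_s = 1 - 6 * sum(d_i^2) / (n * (n^2 - 1)),   d_i = rank_x(i) - rank_y(i)

is evaluated on the two rank vectors.  The closed form is used exactly as
stated, without a tie correction; with minimum-order ranks and ties the
result can fall slightly outside [-1, 1], and no clamping is applied.

The clustering objectives consume a single pluggable distance: plain
Euclidean on raw profiles, or the Spearman distance 1 - r_s computed on the
rank transforms (range [0, 2]).  Centroids live in raw expression space
under both metrics and are rank-transformed on the fly for comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .exceptions import DomainError, ShapeError

__all__ = [
    "METRICS",
    "min_rank_transform",
    "rank_matrix",
    "spearman_coefficient",
    "distance",
    "pairwise_distances",
]

METRICS = ("euclidean", "spearman")


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise DomainError(f"unknown metric {metric!r}; expected one of {METRICS}")


def min_rank_transform(row) -> np.ndarray:
    """Minimum-order ranks of one profile: rank(v) = 1 + #{values < v}.

    Tied values all receive the smallest rank of the tied group, so a
    strictly increasing input of length f maps to 1..f.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise DomainError("rank transform needs a 1-D profile of length >= 2")
    if not np.all(np.isfinite(row)):
        raise DomainError("rank transform requires finite values")
    return rankdata(row, method="min").astype(float)


def rank_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise minimum-order ranks of a 2-D matrix."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DomainError("rank transform requires finite values")
    return rankdata(values, method="min", axis=1).astype(float)


def spearman_coefficient(x_ranks, y_ranks) -> float:
    """Spearman coefficient from two rank vectors via the 6*sum(d^2) closed form."""
    x = np.asarray(x_ranks, dtype=float)
    y = np.asarray(y_ranks, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"rank vectors differ in shape: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise DomainError("Spearman coefficient needs n >= 2")
    d = x - y
    return 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))


def _spearman_scale(f: int) -> float:
    # 1 - r_s(ra, rb) == 6 * ||ra - rb||^2 / (f (f^2 - 1))
    return 6.0 / (f * (f * f - 1))


def distance(a, b, metric: str = "euclidean") -> float:
    """Distance between two raw profiles under the configured metric."""
    _check_metric(metric)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"profiles differ in shape: {a.shape} vs {b.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    ra = min_rank_transform(a)
    rb = min_rank_transform(b)
    d = ra - rb
    return _spearman_scale(a.size) * float(d @ d)


def pairwise_distances(
    points: np.ndarray,
    centroids: np.ndarray,
    metric: str = "euclidean",
    points_are_ranks: bool = False,
) -> np.ndarray:
    """(n, k) distance table between raw-space points and raw-space centroids.

    Under the spearman metric both sides are rank-transformed row-wise first;
    the Spearman distance is then an affine function of the squared Euclidean
    distance between rank vectors, so it vectorizes through cdist.  Callers
    that evaluate many centroid sets against the same data may rank the data
    once and pass ``points_are_ranks=True``.
    """
    _check_metric(metric)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if points.shape[1] != centroids.shape[1]:
        raise ShapeError(
            f"feature mismatch: points f={points.shape[1]}, "
            f"centroids f={centroids.shape[1]}"
        )
    from scipy.spatial.distance import cdist

    if metric == "euclidean":
        return cdist(points, centroids)
    f = points.shape[1]
    rp = points if points_are_ranks else rank_matrix(points)
    rc = rank_matrix(centroids)
    return _spearman_scale(f) * cdist(rp, rc, metric="sqeuclidean")
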