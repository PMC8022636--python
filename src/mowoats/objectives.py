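"""Nearest-centroid assignment and the three clustering objectives.

A candidate clustering is a set of k centroids in raw expression space.  Its
quality is scored by three complementary indices computed from each point's
nearest and second-nearest centroid distances:

* Xie-Beni index (XB, minimize): total squared within-cluster distance over
  n times the minimum squared centroid separation.
* Overall deviation (Dev, minimize): summed distance of every point to its
  assigned centroid.
* Simple Silhouette index (SSI, maximize): mean of 1 - a'/b' where a' is
  the distance to the nearest (own) centroid and b' the distance to the
  nearest other centroid.  Unlike the full Silhouette it needs only
  point-to-centroid distances, so it decomposes over data partitions.

Evaluation follows a map/reduce contract: the data rows are split into
partitions, each partition independently reports (row index, nearest
centroid index, nearest distance, second-nearest distance) tuples, and the
coordinator merges them and applies the three formulas.  The result is
independent of the partition count up to floating-point summation order.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSolutionError, DomainError, ShapeError, StateError
from .expression_io import ExpressionMatrix
from .similarity import pairwise_distances

__all__ = [
    "ObjectiveVector",
    "Solution",
    "Assignment",
    "assign_points",
    "xie_beni",
    "overall_deviation",
    "simple_silhouette",
    "evaluate_objectives",
    "EvaluationBackend",
    "SerialBackend",
    "ProcessPoolBackend",
    "map_partition",
]


@dataclass(frozen=True)
class ObjectiveVector:
    """The three objective values of one solution (xb, dev minimized; ssi maximized)."""

    xb: float
    dev: float
    ssi: float

    def as_min_array(self) -> np.ndarray:
        """All-minimization view used for dominance and crowding (ssi negated)."""
        return np.array([self.xb, self.dev, -self.ssi])

    def astuple(self) -> tuple[float, float, float]:
        return (self.xb, self.dev, self.ssi)


@dataclass
class Solution:
    """k centroid vectors in raw expression space plus (optionally) their objectives."""

    centroids: np.ndarray
    objectives: ObjectiveVector | None = None

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.centroids.shape[0] < 2:
            raise DomainError("a solution needs k >= 2 centroids")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def copy(self) -> "Solution":
        return Solution(self.centroids.copy(), self.objectives)


@dataclass(frozen=True)
class Assignment:
    """Per-point nearest-centroid index and the two smallest centroid distances."""

    i_min: np.ndarray  # (n,) int
    d_min1: np.ndarray  # (n,) float, distance to nearest centroid
    d_min2: np.ndarray  # (n,) float, distance to second-nearest centroid

    @property
    def n(self) -> int:
        return self.i_min.size


def _as_values(data) -> np.ndarray:
    return data.values if isinstance(data, ExpressionMatrix) else np.asarray(data, float)


def map_partition(
    rows: np.ndarray,
    offset: int,
    centroids: np.ndarray,
    metric: str,
    rows_are_ranks: bool = False,
) -> list[tuple[int, int, float, float]]:
    """Map side of the evaluation contract for one contiguous row block.

    Returns one ``(row index, i_min, d_min1, d_min2)`` record per row, keyed
    by the global row index (``offset`` + local position).
    """
    D = pairwise_distances(rows, centroids, metric, points_are_ranks=rows_are_ranks)
    i_min = np.argmin(D, axis=1)  # ties -> lowest index
    part = np.partition(D, 1, axis=1)
    return [
        (offset + i, int(i_min[i]), float(part[i, 0]), float(part[i, 1]))
        for i in range(D.shape[0])
    ]


def _merge_records(records, n: int) -> Assignment:
    i_min = np.empty(n, dtype=int)
    d1 = np.empty(n, dtype=float)
    d2 = np.empty(n, dtype=float)
    seen = 0
    for idx, im, a, b in records:
        i_min[idx], d1[idx], d2[idx] = im, a, b
        seen += 1
    if seen != n:
        raise StateError(f"partition merge produced {seen} records for n={n}")
    return Assignment(i_min, d1, d2)


class EvaluationBackend(ABC):
    """Partitioned objective-evaluation backend.

    Concrete backends split the data rows into ``n_partitions`` contiguous
    blocks, run :func:`map_partition` on each (serially, in a process pool,
    or on a distributed map/reduce engine), and concatenate the keyed
    records.  All backends must produce identical assignments.
    """

    def __init__(self, n_partitions: int = 1):
        if n_partitions < 1:
            raise DomainError("n_partitions must be >= 1")
        self.n_partitions = n_partitions

    def _partition_tasks(self, values: np.ndarray):
        n = values.shape[0]
        bounds = np.linspace(0, n, min(self.n_partitions, n) + 1).astype(int)
        return [(values[a:b], int(a)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    @abstractmethod
    def _map(self, tasks, centroids, metric, rows_are_ranks):
        """Run map_partition over the tasks; return the list of record lists."""

    def assign(
        self,
        values: np.ndarray,
        centroids: np.ndarray,
        metric: str,
        values_are_ranks: bool = False,
    ) -> Assignment:
        if centroids.shape[0] < 2:
            raise DomainError("second-nearest distance undefined for k < 2")
        tasks = self._partition_tasks(values)
        records: list[tuple[int, int, float, float]] = []
        for part in self._map(tasks, centroids, metric, values_are_ranks):
            records.extend(part)
        return _merge_records(records, values.shape[0])


class SerialBackend(EvaluationBackend):
    """Single-process evaluation (the default)."""

    def _map(self, tasks, centroids, metric, rows_are_ranks):
        return [
            map_partition(rows, off, centroids, metric, rows_are_ranks)
            for rows, off in tasks
        ]


class ProcessPoolBackend(EvaluationBackend):
    """Evaluation over a local process pool (joblib)."""

    def __init__(self, n_partitions: int = 4, n_jobs: int | None = None):
        super().__init__(n_partitions)
        self.n_jobs = n_jobs if n_jobs is not None else n_partitions

    def _map(self, tasks, centroids, metric, rows_are_ranks):
        from joblib import Parallel, delayed

        return Parallel(n_jobs=self.n_jobs)(
            delayed(map_partition)(rows, off, centroids, metric, rows_are_ranks)
            for rows, off in tasks
        )


def assign_points(
    data,
    centroids: np.ndarray,
    metric: str = "euclidean",
    backend: EvaluationBackend | None = None,
    values_are_ranks: bool = False,
) -> Assignment:
    """Nearest- and second-nearest-centroid assignment for every data row."""
    values = _as_values(data)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if values.shape[1] != centroids.shape[1]:
        raise ShapeError(
            f"feature mismatch: data f={values.shape[1]}, "
            f"centroids f={centroids.shape[1]}"
        )
    backend = backend or SerialBackend()
    return backend.assign(values, centroids, metric, values_are_ranks)


def xie_beni(
    assignment: Assignment,
    centroids: np.ndarray,
    metric: str = "euclidean",
    n: int | None = None,
) -> float:
    """Compactness / minimum-separation ratio; lower is better.

    sum_i d_min1(i)^2 / (n * min_{k != l} D(C_k, C_l)^2).  Coincident
    centroids make the denominator zero and raise a degeneracy error.
    """
    n = assignment.n if n is None else n
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    D = pairwise_distances(centroids, centroids, metric)
    k = centroids.shape[0]
    off_diag = D[~np.eye(k, dtype=bool)]
    sep = float(off_diag.min())
    if sep == 0.0:
        raise DegenerateSolutionError("coincident centroids: Xie-Beni undefined")
    num = float(assignment.d_min1 @ assignment.d_min1)
    return num / (n * sep * sep)


def overall_deviation(assignment: Assignment) -> float:
    """Summed distance of every point to its assigned centroid; lower is better."""
    return float(assignment.d_min1.sum())


def simple_silhouette(assignment: Assignment) -> float:
    """Mean of 1 - d_min1/d_min2 over all points; in [0, 1] and higher is better.

    A point equidistant from two centroids scores 0; a point coincident with
    two centroids (d_min2 = 0) is given the neutral score 0.
    """
    d1, d2 = assignment.d_min1, assignment.d_min2
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(d2 > 0.0, 1.0 - d1 / np.where(d2 > 0.0, d2, 1.0), 0.0)
    return float(ss.mean())


def evaluate_objectives(
    solution: Solution,
    data,
    metric: str = "euclidean",
    backend: EvaluationBackend | None = None,
    values_are_ranks: bool = False,
) -> ObjectiveVector:
    """Evaluate (XB, Dev, SSI) for a solution through the partition contract.

    The objective vector is independent of the backend's partition count up
    to floating summation order (relative ~1e-9).
    """
    values = _as_values(data)
    asg = assign_points(values, solution.centroids, metric, backend, values_are_ranks)
    obj = ObjectiveVector(
        xb=xie_beni(asg, solution.centroids, metric, n=values.shape[0]),
        dev=overall_deviation(asg),
        ssi=simple_silhouette(asg),
    )
    solution.objectives = obj
    return obj
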