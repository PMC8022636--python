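"""Pareto dominance and the bounded elite list (tabu-search memory).

The elite list (EL) stores mutually non-dominated solutions found so far and
supplies the guide ("leading whale") for swarm moves.  Dominance is over the
three objectives on their natural scales: u dominates v iff u.xb <= v.xb,
u.dev <= v.dev and u.ssi >= v.ssi with at least one strict inequality
(internally ssi is negated so all objectives minimize).  When an insertion
pushes the archive past capacity, the member with the smallest crowding
distance is dropped; per-objective extreme members have infinite crowding
distance and are never dropped, which keeps the stored front spread out.
Candidates whose objective vector already appears in the list are rejected:
duplicates waste capacity without adding information.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, StateError
from .objectives import ObjectiveVector, Solution

__all__ = ["dominates", "crowding_distance", "EliteList"]


def dominates(u: ObjectiveVector, v: ObjectiveVector) -> bool:
    """True iff u Pareto-dominates v (no worse everywhere, better somewhere)."""
    a, b = u.as_min_array(), v.as_min_array()
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("dominance requires finite objective vectors")
    return bool(np.all(a <= b) and np.any(a < b))


def crowding_distance(points: Sequence[ObjectiveVector]) -> np.ndarray:
    """Per-point crowding distances: summed normalized gaps to the sorted
    neighbors in each objective; per-objective extremes get +inf."""
    m = len(points)
    if m == 0:
        raise DomainError("crowding distance needs at least one point")
    arr = np.array([p.as_min_array() for p in points])  # (m, 3)
    dist = np.zeros(m)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = arr[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0 and m > 2:
            gaps = (col[2:] - col[:-2]) / span
            dist[order[1:-1]] += gaps
    return dist


class EliteList:
    """Bounded archive of mutually non-dominated solutions."""

    def __init__(self, capacity: int = 50):
        if capacity < 1:
            raise DomainError("elite-list capacity must be positive")
        self.capacity = capacity
        self.solutions: list[Solution] = []

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def objective_vectors(self) -> list[ObjectiveVector]:
        return [s.objectives for s in self.solutions]

    def update(self, candidate: Solution) -> bool:
        """Offer a candidate; return True iff the membership changed.

        Rejected when any member dominates the candidate or shares its exact
        objective vector; otherwise members dominated by the candidate are
        removed, the candidate is inserted, and a crowding-based truncation
        enforces the capacity bound.
        """
        if candidate.objectives is None:
            raise StateError("candidate must be evaluated before archiving")
        cobj = candidate.objectives
        for member in self.solutions:
            if member.objectives.astuple() == cobj.astuple() or dominates(
                member.objectives, cobj
            ):
                return False
        survivors = [s for s in self.solutions if not dominates(cobj, s.objectives)]
        removed_any = len(survivors) != len(self.solutions)
        self.solutions = survivors
        self.solutions.append(candidate)
        if len(self.solutions) > self.capacity:
            dist = crowding_distance(self.objective_vectors())
            evicted = self.solutions.pop(int(np.argmin(dist)))
            if evicted is candidate and not removed_any:
                return False  # membership identical to before the offer
        return True

    def update_many(self, candidates: Iterable[Solution]) -> bool:
        changed = False
        for c in candidates:
            changed |= self.update(c)
        return changed

    def to_frame(self) -> pd.DataFrame:
        """Flattened centroids + objectives, one row per archived solution."""
        rows = []
        for s in self.solutions:
            row = {
                f"c{i}_{j}": s.centroids[i, j]
                for i in range(s.centroids.shape[0])
                for j in range(s.centroids.shape[1])
            }
            row.update(xb=s.objectives.xb, dev=s.objectives.dev, ssi=s.objectives.ssi)
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")
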