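"""The MOWOATS main loop: whale-optimization moves guided by the elite list.

Each whale is a candidate clustering encoded as k centroids (a flattened
k*f position vector).  Every iteration each whale draws fresh coefficients
and moves by one of three rules:

* encircling a random elite-list member (intensification; p above the
  threshold and the attraction coefficient small),
* encircling a random swarm member (exploration; attraction coefficient
  large), or
* a logarithmic bubble-net spiral around a random elite-list member
  (exploitation; p at or below the threshold).

Positions are clamped to the per-feature data range, re-evaluated on the
three objectives, and offered to the elite list.  When the elite list has
not changed for ``max_non_improve`` consecutive iterations, a crossover
phase swaps random centroid subsets between whales and either elite-list
members (intensification) or other whales (diversification), restarting the
search from recombined solutions.  The final elite list holds the
non-dominated clusterings found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateSolutionError, DomainError, ShapeError
from .expression_io import ExpressionMatrix
from .objectives import (
    EvaluationBackend,
    SerialBackend,
    Solution,
    evaluate_objectives,
)
from .pareto_archive import EliteList
from .similarity import METRICS, rank_matrix

__all__ = [
    "AlgorithmConfig",
    "WOAParams",
    "init_population",
    "woa_update_params",
    "woa_encircle",
    "woa_spiral",
    "mowoats_step",
    "crossover_solutions",
    "crossover_phase",
    "run_mowoats",
]

logger = logging.getLogger("mowoats")


@dataclass
class AlgorithmConfig:
    """Run parameters.

    Defaults follow the method's published setting: 50 iterations, 15
    whales, elite-list capacity 50, stagnation threshold 2, branch
    probability threshold 0.2 and spiral shape constant b = 1.
    """

    k: int
    metric: str = "euclidean"
    max_it: int = 50
    n_whales: int = 15  # Np
    max_el: int = 50
    max_non_improve: int = 2
    p_threshold: float = 0.2
    spiral_b: float = 1.0
    seed: int | None = None
    bounds: np.ndarray | None = None  # (f, 2) per-feature [min, max]
    exploit_move: str = "spiral"  # move used on the p <= threshold branch

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DomainError("k must be >= 2")
        if self.max_it < 1 or self.n_whales < 2:
            raise DomainError("need max_it >= 1 and n_whales >= 2")
        if not 0.0 < self.p_threshold < 1.0:
            raise DomainError("p_threshold must lie strictly in (0, 1)")
        if self.metric not in METRICS:
            raise DomainError(f"metric must be one of {METRICS}")
        if self.exploit_move not in ("spiral", "encircle"):
            raise DomainError("exploit_move must be 'spiral' or 'encircle'")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)

    @property
    def dim(self) -> int:
        if self.bounds is None:
            raise DomainError("bounds unset; dimension unknown")
        return self.k * self.bounds.shape[0]

    def with_bounds_from(self, values: np.ndarray) -> "AlgorithmConfig":
        bounds = np.column_stack([values.min(axis=0), values.max(axis=0)])
        return replace(self, bounds=bounds)


@dataclass(frozen=True)
class WOAParams:
    """One whale's per-iteration stochastic coefficients.

    ``a`` decays linearly 2 -> 0 over iterations; ``A = 2a*r - a`` and
    ``C = 2r'`` are drawn per dimension; ``l`` is uniform in [-1, 1];
    ``p`` and ``theta`` are uniform in [0, 1].
    """

    a: float
    A: np.ndarray
    C: np.ndarray
    l: float
    p: float
    theta: float

    @property
    def attraction(self) -> float:
        """Scalar magnitude of A used for the intensify/explore branch."""
        return float(np.abs(self.A).mean())


def init_population(
    data, config: AlgorithmConfig, rng: np.random.Generator
) -> list[Solution]:
    """Np solutions, each of k distinct data rows sampled without replacement."""
    values = data.values if isinstance(data, ExpressionMatrix) else np.asarray(data)
    n = values.shape[0]
    if n < config.k:
        raise DomainError(f"cannot draw k={config.k} distinct rows from n={n}")
    return [
        Solution(values[rng.choice(n, size=config.k, replace=False)].copy())
        for _ in range(config.n_whales)
    ]


def woa_update_params(
    t: int, config: AlgorithmConfig, rng: np.random.Generator
) -> WOAParams:
    """Draw the iteration-t coefficients (a, A, C, l, p, theta)."""
    if not 0 <= t < config.max_it:
        raise DomainError(f"iteration {t} outside [0, {config.max_it})")
    a = 2.0 * (1.0 - t / config.max_it)
    dim = config.dim
    A = 2.0 * a * rng.random(dim) - a
    C = 2.0 * rng.random(dim)
    l = rng.uniform(-1.0, 1.0)
    p = rng.random()
    theta = rng.random()
    return WOAParams(a=a, A=A, C=C, l=l, p=p, theta=theta)


def _check_lengths(position, guide) -> tuple[np.ndarray, np.ndarray]:
    position = np.asarray(position, dtype=float).ravel()
    guide = np.asarray(guide, dtype=float).ravel()
    if position.shape != guide.shape:
        raise ShapeError(f"position {position.shape} vs guide {guide.shape}")
    return position, guide


def woa_encircle(position, guide, A, C) -> np.ndarray:
    """Shrinking-encircling move: new_j = guide_j - A_j * |C_j*guide_j - position_j|."""
    position, guide = _check_lengths(position, guide)
    D = np.abs(np.asarray(C) * guide - position)
    return guide - np.asarray(A) * D


def woa_spiral(position, guide, l: float, spiral_b: float = 1.0) -> np.ndarray:
    """Bubble-net spiral: new_j = |guide_j - position_j| * e^{b l} cos(2 pi l) + guide_j."""
    position, guide = _check_lengths(position, guide)
    D = np.abs(guide - position)
    return D * np.exp(spiral_b * l) * np.cos(2.0 * np.pi * l) + guide


def _clamp(flat: np.ndarray, config: AlgorithmConfig) -> np.ndarray:
    cent = flat.reshape(config.k, -1)
    return np.clip(cent, config.bounds[:, 0], config.bounds[:, 1])


def _evaluate_and_offer(
    solution: Solution, el: EliteList, eval_data, config, backend, values_are_ranks
) -> bool:
    """Evaluate a solution and offer it to the elite list.

    Degenerate solutions (coincident centroids) are kept in the swarm but
    never archived.
    """
    try:
        evaluate_objectives(
            solution, eval_data, config.metric, backend, values_are_ranks
        )
    except DegenerateSolutionError:
        solution.objectives = None
        return False
    return el.update(solution)


def mowoats_step(
    swarm: list[Solution],
    el: EliteList,
    t: int,
    config: AlgorithmConfig,
    data,
    rng: np.random.Generator,
    backend: EvaluationBackend | None = None,
    eval_values: np.ndarray | None = None,
    values_are_ranks: bool = False,
) -> bool:
    """One main-loop iteration over every whale; returns True iff EL changed.

    ``eval_values``/``values_are_ranks`` let callers reuse a precomputed
    rank matrix under the spearman metric; by default the raw data is used.
    """
    if len(el) == 0:
        raise DomainError("elite list must be non-empty before stepping")
    values = data.values if isinstance(data, ExpressionMatrix) else np.asarray(data)
    eval_data = values if eval_values is None else eval_values
    changed = False
    for i, whale in enumerate(swarm):
        params = woa_update_params(t, config, rng)
        pos = whale.centroids.ravel()
        if params.p > config.p_threshold:
            if params.attraction < 1.0:
                guide = el.solutions[rng.integers(len(el))].centroids.ravel()
            else:
                guide = swarm[rng.integers(len(swarm))].centroids.ravel()
            new = woa_encircle(pos, guide, params.A, params.C)
        else:
            guide = el.solutions[rng.integers(len(el))].centroids.ravel()
            if config.exploit_move == "spiral":
                new = woa_spiral(pos, guide, params.l, config.spiral_b)
            else:
                new = woa_encircle(pos, guide, params.A, params.C)
        moved = Solution(_clamp(new, config))
        changed |= _evaluate_and_offer(
            moved, el, eval_data, config, backend, values_are_ranks
        )
        swarm[i] = moved
    return changed


def crossover_solutions(
    s1: Solution, s2: Solution, rng: np.random.Generator
) -> Solution:
    """Offspring = s1 with a random non-empty proper subset of centroid slots
    replaced by s2's centroids at the same slots; objectives unset."""
    if s1.k != s2.k or s1.centroids.shape != s2.centroids.shape:
        raise ShapeError("parents must share k and f")
    k = s1.k
    m = int(rng.integers(1, k))  # uniform in [1, k-1]
    idx = rng.choice(k, size=m, replace=False)
    child = s1.centroids.copy()
    child[idx] = s2.centroids[idx]
    return Solution(child)


def crossover_phase(
    swarm: list[Solution],
    el: EliteList,
    theta: float,
    rng: np.random.Generator,
) -> list[int]:
    """Recombine q randomly chosen whales (q <= Np // 2) in place.

    theta < 0.5: each chosen whale is crossed with a random elite-list
    member (intensification); otherwise with a different random swarm
    member (diversification).  Returns the indices of replaced whales,
    which the caller must re-evaluate.
    """
    n_whales = len(swarm)
    q = int(rng.integers(1, max(n_whales // 2, 1) + 1))
    chosen = rng.choice(n_whales, size=q, replace=False)
    for i in chosen:
        if theta < 0.5 and len(el) > 0:
            partner = el.solutions[rng.integers(len(el))]
        else:
            j = int(rng.integers(n_whales - 1))
            j = j + 1 if j >= i else j  # a *different* swarm member
            partner = swarm[j]
        swarm[int(i)] = crossover_solutions(swarm[int(i)], partner, rng)
    return [int(i) for i in chosen]


def run_mowoats(
    data,
    config: AlgorithmConfig,
    backend: EvaluationBackend | None = None,
) -> EliteList:
    """Full optimization run; returns the final elite list.

    All randomness flows from a single generator seeded by ``config.seed``,
    so identical configs reproduce identical elite lists bit for bit.
    """
    values = data.values if isinstance(data, ExpressionMatrix) else np.asarray(data)
    values = np.asarray(values, dtype=float)
    if config.bounds is None:
        config = config.with_bounds_from(values)
    if values.shape[0] < config.k:
        raise DomainError(f"n={values.shape[0]} rows < k={config.k}")
    rng = np.random.default_rng(config.seed)
    backend = backend or SerialBackend()

    values_are_ranks = config.metric == "spearman"
    eval_values = rank_matrix(values) if values_are_ranks else values

    el = EliteList(capacity=config.max_el)
    swarm = init_population(values, config, rng)
    for whale in swarm:
        _evaluate_and_offer(whale, el, eval_values, config, backend, values_are_ranks)
    if len(el) == 0:
        raise DegenerateSolutionError(
            "no valid initial solution (all centroid sets degenerate)"
        )

    stagnation = 0
    for t in range(config.max_it):
        changed = mowoats_step(
            swarm, el, t, config, data, rng, backend, eval_values, values_are_ranks
        )
        stagnation = 0 if changed else stagnation + 1
        if stagnation >= config.max_non_improve:
            theta = rng.random()
            replaced = crossover_phase(swarm, el, theta, rng)
            for i in replaced:
                changed = _evaluate_and_offer(
                    swarm[i], el, eval_values, config, backend, values_are_ranks
                )
            stagnation = 0
        if logger.isEnabledFor(logging.DEBUG):
            objs = np.array([o.as_min_array() for o in el.objective_vectors()])
            logger.debug(
                "iter=%d el_size=%d best_xb=%.4g best_dev=%.4g best_ssi=%.4g "
                "stagnation=%d",
                t, len(el), objs[:, 0].min(), objs[:, 1].min(), -objs[:, 2].min(),
                stagnation,
            )
    return el
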