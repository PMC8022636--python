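"""Synthetic expression-like datasets with known cluster structure.

Real microarray inputs for this kind of clustering are complete, pre-
normalized n-gene x f-feature matrices (a few hundred genes, < 20 time
points, a handful of co-expression groups).  The generator emulates that
shape with k latent groups in two flavours:

* ``blob``: group centroids placed in feature space with a guaranteed
  pairwise separation (in units of the noise standard deviation), points =
  centroid + isotropic Gaussian noise;
* ``timecourse``: smooth z-scored group templates over ordered features
  (rising, falling, peaked, sinusoidal, then phase-shifted sinusoids for
  k > 4) plus Gaussian noise, mimicking normalized log-ratio trajectories
  so rank/Spearman behaviour is driven by curve shape, not magnitude.

``tie_fraction`` quantizes that share of entries to two decimals to force
rank ties, exercising the minimum-order tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, GenerationError
from .expression_io import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_genes: int = 400
    n_features: int = 10
    k: int = 4
    group_weights: tuple[float, ...] | None = None  # uniform when None
    separation: float = 10.0  # minimum centroid spacing, in noise-sigma units
    noise_sigma: float = 1.0
    profile_shape: str = "blob"  # or "timecourse"
    tie_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise DomainError("k must be >= 2")
        if self.n_genes < self.k or self.n_features < 2:
            raise DomainError("need n_genes >= k and n_features >= 2")
        if self.separation <= 0:
            raise DomainError("separation must be positive")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be non-negative")
        if not 0.0 <= self.tie_fraction <= 1.0:
            raise DomainError("tie_fraction must lie in [0, 1]")
        if self.profile_shape not in ("blob", "timecourse"):
            raise DomainError("profile_shape must be 'blob' or 'timecourse'")
        if self.group_weights is not None:
            w = tuple(float(x) for x in self.group_weights)
            if len(w) != self.k or any(x <= 0 for x in w):
                raise DomainError("group_weights must be k positive numbers")
            total = sum(w)
            object.__setattr__(
                self, "group_weights", tuple(x / total for x in w)
            )

    @property
    def weights(self) -> np.ndarray:
        if self.group_weights is None:
            return np.full(self.k, 1.0 / self.k)
        return np.asarray(self.group_weights)


def _blob_centroids(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample k centroids with pairwise distance >= separation*sigma."""
    min_dist = spec.separation * max(spec.noise_sigma, 1e-12)
    scale = max(min_dist, 1.0)
    for _ in range(1000):
        cand = rng.normal(0.0, scale, size=(spec.k, spec.n_features))
        diffs = cand[:, None, :] - cand[None, :, :]
        d = np.sqrt((diffs**2).sum(-1))
        if d[~np.eye(spec.k, dtype=bool)].min() >= min_dist:
            return cand
    raise GenerationError(
        f"could not place {spec.k} centroids at separation {min_dist} "
        f"in {spec.n_features} dimensions within 1000 attempts"
    )


def _timecourse_templates(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """k smooth z-scored trajectories over f ordered pseudo-time points."""
    f = spec.n_features
    t = np.linspace(0.0, 1.0, f)
    base = [
        t,                                   # rising
        1.0 - t,                             # falling
        np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2),  # peaked
        np.sin(2.0 * np.pi * t),             # sinusoidal
    ]
    templates = []
    for g in range(spec.k):
        if g < 4:
            curve = base[g]
        else:  # phase-shifted sinusoids for additional groups
            curve = np.sin(2.0 * np.pi * (t + g / spec.k))
        curve = np.asarray(curve, dtype=float)
        sd = curve.std()
        curve = (curve - curve.mean()) / (sd if sd > 0 else 1.0)
        templates.append(curve)
    # scale template spread so group separation matches the blob convention
    scale = spec.separation * max(spec.noise_sigma, 1e-12) / np.sqrt(2.0 * f)
    return np.stack(templates) * max(scale, 1.0)


def _ensure_row_tie(values: np.ndarray) -> None:
    """Guarantee at least one within-row tie after quantization.

    Wide-spread profiles may quantize without collisions; in that case the
    two closest entries of the first row are set to a common rounded value
    so rank-tie handling is always exercised.
    """
    for row in values:
        if np.unique(row).size < row.size:
            return
    row = values[0]
    order = np.argsort(row)
    gaps = np.diff(row[order])
    i = int(np.argmin(gaps))
    a, b = order[i], order[i + 1]
    row[a] = row[b] = np.round(0.5 * (row[a] + row[b]), 2)


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one dataset; returns the matrix and the generating labels."""
    rng = np.random.default_rng(spec.seed)
    if spec.profile_shape == "blob":
        centroids = _blob_centroids(spec, rng)
    else:
        centroids = _timecourse_templates(spec, rng)
    labels = rng.choice(spec.k, size=spec.n_genes, p=spec.weights)
    values = centroids[labels] + rng.normal(
        0.0, spec.noise_sigma, size=(spec.n_genes, spec.n_features)
    )
    if spec.tie_fraction > 0.0:
        mask = rng.random(values.shape) < spec.tie_fraction
        values[mask] = np.round(values[mask], 2)
        _ensure_row_tie(values)
    gene_ids = tuple(f"G{i:05d}" for i in range(spec.n_genes))
    feature_labels = tuple(f"t{j}" for j in range(spec.n_features))
    return ExpressionMatrix(gene_ids, feature_labels, values), labels
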