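"""Synthetic ground truth: structures, simulated contact maps, and noise.

The generator provides the controlled conditions the reconstruction method
assumes: a known 3D curve (a regular helix by default — smooth and
chromosome-like in its locality — or a unit-step random walk for stress
tests), a contact map simulated from it by the inverse power law
``IF = 1/D^alpha``, and multiplicative uniform noise at a chosen percentage
level mirroring robustness ladders of 3%–40%. Because the map is built from
the exact formula the conversion step inverts, recovering the generating
alpha and the generating geometry is a well-posed end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import ContactMatrix, Structure, ValidationError
from .metrics import pairwise_distances

__all__ = ["NoiseSpec", "generate_structure", "structure_to_if", "add_noise"]

STRUCTURE_KINDS = ("helix", "random_walk")

#: helix geometry: unit radius, 20 beads per turn, rise of 0.2 per bead —
#: a smooth non-self-intersecting curve with equal consecutive-bead spacing
HELIX_RADIUS = 1.0
HELIX_STEP_ANGLE = 2.0 * np.pi / 20.0
HELIX_RISE = 0.2


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative noise: each IF entry is scaled by ``1 + u`` with
    ``u ~ U(-level, +level)`` drawn once per unordered pair."""

    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValidationError("noise level must be nonnegative")


def generate_structure(n_bins: int, kind: str = "helix", seed: int = 0) -> Structure:
    """Deterministic ground-truth curve with one bead per bin.

    ``helix`` places beads on a regular helix (seed only perturbs the phase
    so different seeds give rotated copies); ``random_walk`` takes unit
    steps in uniformly random directions.
    """
    if n_bins < 4:
        raise ValidationError("need at least 4 bins")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_bins)
        theta = phase + HELIX_STEP_ANGLE * t
        coords = np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * t]
        )
    elif kind == "random_walk":
        steps = rng.normal(size=(n_bins - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise ValidationError(
            f"unknown structure kind {kind!r}; expected one of {STRUCTURE_KINDS}"
        )
    return Structure(coords)


def structure_to_if(structure: Structure, alpha: float = 1.0) -> ContactMatrix:
    """Simulate a contact map from a structure: ``IF(i,j) = 1/D(i,j)^alpha``
    for i != j, zero diagonal."""
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    n = structure.n_beads
    d = pairwise_distances(structure)
    if np.any(d <= 0):
        raise ValidationError("coincident beads give degenerate distances")
    values = np.zeros((n, n))
    i, j = np.triu_indices(n, k=1)
    values[i, j] = values[j, i] = 1.0 / d**alpha
    return ContactMatrix(values)


def add_noise(matrix: ContactMatrix, spec: NoiseSpec) -> ContactMatrix:
    """Perturb each unordered pair by an independent relative amount in
    ``[-level, +level]``, preserving symmetry; results clipped at 0."""
    rng = np.random.default_rng(spec.seed)
    n = matrix.n_bins
    i, j = np.triu_indices(n, k=1)
    u = rng.uniform(-spec.level, spec.level, size=i.size)
    values = matrix.values.copy()
    perturbed = np.clip(values[i, j] * (1.0 + u), 0.0, None)
    values[i, j] = values[j, i] = perturbed
    return ContactMatrix(values, resolution=matrix.resolution, bin_ids=matrix.bin_ids)
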