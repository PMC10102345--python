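"""Diffusion acquisition schemes (b-values and encoding directions).

An acquisition scheme lists, per acquired volume, the diffusion-weighting
strength *b* (s/mm²) and the unit gradient direction *g*. Volumes with b = 0
carry no diffusion weighting and may use a zero direction vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionScheme", "default_scheme", "fibonacci_directions"]

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm²) and unit gradient directions.

    Invariants (enforced at construction): b-values are non-negative; every
    direction attached to a diffusion-weighted volume has unit Euclidean norm
    within 1e-6 (b = 0 volumes may carry the zero vector); both arrays have
    one entry per volume.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float).reshape(-1)
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError(f"directions must be (n, 3); got {g.shape}")
        if g.shape[0] != b.shape[0]:
            raise ValueError(
                f"{b.shape[0]} b-values but {g.shape[0]} directions"
            )
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(g, axis=1)
        weighted = b > 0
        bad = weighted & (np.abs(norms - 1.0) > _NORM_TOL)
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} diffusion-weighted direction(s) are not unit vectors"
            )
        # b=0 rows may be zero or unit vectors; anything else is malformed
        b0_bad = ~weighted & (norms > _NORM_TOL) & (np.abs(norms - 1.0) > _NORM_TOL)
        if np.any(b0_bad):
            raise ValueError("b=0 directions must be zero or unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    @property
    def volume_count(self) -> int:
        return int(self.b_values.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    def subset(self, index: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to the given volume indices, order preserved."""
        return AcquisitionScheme(self.b_values[index], self.directions[index])


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` well-spread unit vectors from a spherical Fibonacci lattice.

    Deterministic; points are near-uniform over the sphere, an adequate stand-in
    for electrostatic-repulsion direction tables.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * k / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_scheme(
    n_directions: int = 128,
    n_shells: int = 17,
    b_max: float = 3000.0,
) -> AcquisitionScheme:
    """Multi-shell scheme emulating a DSI-style acquisition.

    One b = 0 volume plus ``n_directions`` diffusion-weighted volumes whose
    b-values cycle through ``n_shells`` evenly spaced non-zero shells up to
    ``b_max`` — 129 volumes, 18 distinct b-values and 128 distinct directions
    at the defaults.
    """
    nonzero = np.round(np.linspace(0.0, b_max, n_shells + 1)[1:])
    dirs = fibonacci_directions(n_directions)
    b = np.concatenate([[0.0], nonzero[np.arange(n_directions) % n_shells]])
    g = np.vstack([np.zeros(3), dirs])
    return AcquisitionScheme(b, g)
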