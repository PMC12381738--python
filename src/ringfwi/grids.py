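"""Cartesian grids and the scalar fields defined on them.

The imaging domain is a small Cartesian box (2D slice or 3D volume) with
isotropic spacing; the unknown of the inversion is acoustic slowness
(reciprocal sound speed, s/m) sampled on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "SlownessField", "SourceField", "HelmholtzSolution"]

#: sanity range for tissue/water sound speeds, m/s
SPEED_MIN = 500.0
SPEED_MAX = 3000.0


@dataclass(frozen=True)
class Grid:
    """Regular Cartesian grid (2 or 3 axes) with isotropic spacing.

    Parameters
    ----------
    shape
        Number of samples per axis; every extent must be >= 8.
    spacing
        Sample spacing per axis in meters. The Helmholtz solvers require
        isotropic spacing (a single scalar ``h``).
    origin
        Physical coordinate (meters) of the first sample on each axis.
    """

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        shape = tuple(int(n) for n in np.atleast_1d(self.shape))
        ndim = len(shape)
        if ndim not in (2, 3):
            raise ValueError(f"grid must have 2 or 3 axes, got {ndim}")
        if any(n < 8 for n in shape):
            raise ValueError(f"all grid extents must be >= 8, got {shape}")
        spacing = np.broadcast_to(np.asarray(self.spacing, float), (ndim,))
        if np.any(spacing <= 0):
            raise ValueError("grid spacing must be positive")
        origin = np.broadcast_to(np.asarray(self.origin, float), (ndim,))
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", tuple(spacing))
        object.__setattr__(self, "origin", tuple(origin))

    @classmethod
    def centered(cls, shape, spacing):
        """Grid whose coordinate origin is at the center of the box."""
        shape = tuple(int(n) for n in np.atleast_1d(shape))
        spacing = float(np.atleast_1d(spacing)[0])
        origin = tuple(-(n - 1) / 2.0 * spacing for n in shape)
        return cls(shape, (spacing,) * len(shape), origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def h(self) -> float:
        """Isotropic spacing in meters; raises if axes differ."""
        s = np.asarray(self.spacing)
        if not np.allclose(s, s[0], rtol=1e-12, atol=0.0):
            raise ValueError(f"anisotropic spacing {self.spacing}: solvers need a single h")
        return float(s[0])

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axes(self):
        """Per-axis coordinate arrays in meters."""
        return [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(self.ndim)
        ]

    def meshgrid(self):
        return np.meshgrid(*self.axes(), indexing="ij")

    @property
    def extent(self):
        """Physical size of the box per axis (meters)."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def slice2d(self):
        """The (x, y) slice grid sharing this grid's in-plane axes."""
        if self.ndim == 2:
            return self
        return Grid(self.shape[:2], self.spacing[:2], self.origin[:2])


def _check_values(grid: Grid, values, dtype):
    values = np.asarray(values, dtype=dtype)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("field contains non-finite values")
    return values


@dataclass(frozen=True)
class SlownessField:
    """Real acoustic slowness s(x) = 1/c(x) in s/m on a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self):
        values = _check_values(self.grid, self.values, float)
        if np.any(values <= 0):
            raise ValueError("slowness must be strictly positive")
        speed = 1.0 / values
        if speed.min() < SPEED_MIN or speed.max() > SPEED_MAX:
            raise ValueError(
                f"sound speed outside sanity range [{SPEED_MIN}, {SPEED_MAX}] m/s: "
                f"[{speed.min():.1f}, {speed.max():.1f}]"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def homogeneous(cls, grid: Grid, speed_mps: float) -> "SlownessField":
        return cls(grid, np.full(grid.shape, 1.0 / speed_mps))

    @property
    def sound_speed(self) -> np.ndarray:
        """Sound speed in m/s."""
        return 1.0 / self.values


@dataclass(frozen=True)
class SourceField:
    """Complex right-hand side of the Helmholtz equation on a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", _check_values(self.grid, self.values, complex))


@dataclass(frozen=True)
class HelmholtzSolution:
    """Complex pressure field for one source and angular frequency."""

    grid: Grid
    omega: float
    values: np.ndarray
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "values", _check_values(self.grid, self.values, complex))
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
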