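"""Multi-row ring-array geometry and the field sampling operator.

The array is a cylinder of point transducers: ``n_rows`` rings of
``n_elements_per_row`` elements each, rows stacked with a fixed pitch and
centered on the grid axis. A cylindrical-wave transmit fires the same
circumferential element in every row simultaneously, producing a broad
unfocused wavefront that insonifies the whole elevation span.

Elements are ideal points. The sampling operator K extracts the complex
pressure at each element by multilinear interpolation; its transpose injects
receiver-domain residuals back onto the grid as adjoint sources. Sources are
deposited with the same stencil, so K and K^T are exact transposes and
source/receiver reciprocity holds at the discrete level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .grids import Grid, HelmholtzSolution, SourceField

__all__ = [
    "RingArraySpec",
    "TransmitSet",
    "SamplingOperator",
    "element_positions",
    "make_cylindrical_source",
    "sample_field",
    "inject",
]


@dataclass(frozen=True)
class RingArraySpec:
    """Multi-row ring array: radius, rows, elements per row, row pitch (meters).

    Defaults describe a 22-cm-diameter ring of 32 rows x 256 elements with
    2.4 mm row pitch (8192 elements). Element index = row * n_elements_per_row
    + azimuth; azimuth j sits at angle 2*pi*j/n_elements_per_row; row heights
    are symmetric about the ring center.
    """

    radius: float = 0.11
    n_rows: int = 32
    n_elements_per_row: int = 256
    row_pitch: float = 0.0024
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.n_elements_per_row < 3:
            raise ValueError("n_elements_per_row must be >= 3")
        if self.n_rows > 1 and self.row_pitch <= 0:
            raise ValueError("row_pitch must be positive for multi-row arrays")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def n_elements(self) -> int:
        return self.n_rows * self.n_elements_per_row

    def row_heights(self) -> np.ndarray:
        """Element z-coordinates per row, symmetric about the array center."""
        cz = self.center[2] if len(self.center) > 2 else 0.0
        return cz + (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.row_pitch

    def azimuths(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.n_elements_per_row) / self.n_elements_per_row

    def single_row(self, height: float = 0.0) -> "RingArraySpec":
        """A one-row view of this array at a given height (for 2D slices)."""
        return RingArraySpec(
            self.radius, 1, self.n_elements_per_row, self.row_pitch,
            (self.center[0], self.center[1], height),
        )


@dataclass(frozen=True)
class TransmitSet:
    """Azimuthal element indices fired (one per cylindrical-wave transmit)."""

    indices: tuple

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("transmit indices must be unique")
        if any(i < 0 for i in idx):
            raise ValueError("transmit indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def every(cls, spec: RingArraySpec, stride: int = 1) -> "TransmitSet":
        return cls(tuple(range(0, spec.n_elements_per_row, stride)))

    def __len__(self):
        return len(self.indices)

    def validate_against(self, spec: RingArraySpec) -> None:
        if len(self.indices) > spec.n_elements_per_row:
            raise ValueError("more transmits than circumferential elements")
        if any(i >= spec.n_elements_per_row for i in self.indices):
            raise ValueError("transmit index exceeds n_elements_per_row")


def element_positions(spec: RingArraySpec, ndim: int = 3) -> np.ndarray:
    """Element coordinates, shape (n_rows * n_elements_per_row, ndim).

    For ``ndim == 2`` the array must have a single row; positions are the
    in-plane ring coordinates.
    """
    theta = spec.azimuths()
    cx, cy = spec.center[0], spec.center[1]
    ring = np.column_stack([cx + spec.radius * np.cos(theta), cy + spec.radius * np.sin(theta)])
    if ndim == 2:
        if spec.n_rows != 1:
            raise ValueError("2D element positions require a single-row array")
        return ring
    heights = spec.row_heights()
    pos = np.empty((spec.n_rows, spec.n_elements_per_row, 3))
    pos[:, :, :2] = ring[None, :, :]
    pos[:, :, 2] = heights[:, None]
    return pos.reshape(-1, 3)


def _stencil(positions: np.ndarray, grid: Grid, mode: str):
    """Interpolation stencil rows: (element, voxel flat index, weight) triples."""
    positions = np.atleast_2d(np.asarray(positions, float))
    if positions.shape[1] != grid.ndim:
        raise ValueError(
            f"positions have {positions.shape[1]} coordinates but the grid has {grid.ndim} axes"
        )
    frac = (positions - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    if np.any(frac < 0) or np.any(frac > np.asarray(grid.shape) - 1):
        bad = np.where(np.any((frac < 0) | (frac > np.asarray(grid.shape) - 1), axis=1))[0]
        raise ValueError(f"element(s) {bad.tolist()} fall outside the grid interior")
    n_el = positions.shape[0]
    if mode == "nearest":
        idx = np.rint(frac).astype(int)
        flat = np.ravel_multi_index(tuple(idx.T), grid.shape)
        return (
            np.arange(n_el),
            flat,
            np.ones(n_el),
        )
    if mode != "linear":
        raise ValueError(f"unknown stencil {mode!r}")
    lo = np.floor(frac).astype(int)
    lo = np.minimum(lo, np.asarray(grid.shape) - 2)  # keep the 2^d cube in-bounds
    t = frac - lo
    rows, cols, weights = [], [], []
    for corner in np.ndindex(*(2,) * grid.ndim):
        c = np.asarray(corner)
        w = np.prod(np.where(c, t, 1 - t), axis=1)
        flat = np.ravel_multi_index(tuple((lo + c).T), grid.shape)
        rows.append(np.arange(n_el))
        cols.append(flat)
        weights.append(w)
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(weights)


class SamplingOperator:
    """Sparse linear map K from grid fields to per-element samples.

    ``sample`` applies K (fields -> receiver traces); ``inject`` applies the
    exact transpose K^T (receiver residuals -> adjoint source fields). Both
    accept leading batch axes.
    """

    def __init__(self, positions: np.ndarray, grid: Grid, stencil: str = "linear"):
        self.grid = grid
        self.positions = np.atleast_2d(np.asarray(positions, float))
        self.stencil = stencil
        rows, cols, weights = _stencil(self.positions, grid, stencil)
        self.matrix = sp.csr_matrix(
            (weights, (rows, cols)), shape=(self.positions.shape[0], grid.n_voxels)
        )
        self._matrix_t = self.matrix.T.tocsr()

    @classmethod
    def for_array(cls, spec: RingArraySpec, grid: Grid, stencil: str = "linear"):
        return cls(element_positions(spec, grid.ndim), grid, stencil)

    @property
    def n_elements(self) -> int:
        return self.matrix.shape[0]

    def sample(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        if values.shape[-self.grid.ndim :] != self.grid.shape:
            raise ValueError("field shape does not match the sampling grid")
        batch = values.shape[: values.ndim - self.grid.ndim]
        flat = values.reshape(-1, self.grid.n_voxels)
        out = (self.matrix @ flat.T).T
        return out.reshape(batch + (self.n_elements,))

    def inject(self, residual: np.ndarray) -> np.ndarray:
        residual = np.asarray(residual)
        if residual.shape[-1] != self.n_elements:
            raise ValueError(
                f"residual length {residual.shape[-1]} != {self.n_elements} elements"
            )
        batch = residual.shape[:-1]
        flat = residual.reshape(-1, self.n_elements)
        out = (self._matrix_t @ flat.T).T
        return out.reshape(batch + self.grid.shape)


def sample_field(K: SamplingOperator, u) -> np.ndarray:
    """p = K u: complex pressure at every element."""
    values = u.values if isinstance(u, HelmholtzSolution) else u
    return K.sample(values)


def inject(K: SamplingOperator, residual: np.ndarray) -> SourceField:
    """K^T residual deposited onto the grid as an adjoint source."""
    return SourceField(K.grid, K.inject(np.asarray(residual, complex)))


def make_cylindrical_source(
    spec: RingArraySpec, transmit_index: int, grid: Grid, stencil: str = "linear"
) -> SourceField:
    """Unit point sources at one azimuth in every row, deposited on the grid.

    On a 2D grid this degenerates to a single in-plane point source at the
    transmit azimuth.
    """
    if not 0 <= transmit_index < spec.n_elements_per_row:
        raise ValueError(
            f"transmit_index {transmit_index} out of range [0, {spec.n_elements_per_row})"
        )
    theta = 2 * np.pi * transmit_index / spec.n_elements_per_row
    x = spec.center[0] + spec.radius * np.cos(theta)
    y = spec.center[1] + spec.radius * np.sin(theta)
    if grid.ndim == 2:
        positions = np.array([[x, y]])
    else:
        heights = spec.row_heights()
        positions = np.column_stack([np.full_like(heights, x), np.full_like(heights, y), heights])
    rows, cols, weights = _stencil(positions, grid, stencil)
    values = np.zeros(grid.n_voxels, dtype=complex)
    np.add.at(values, cols, weights)
    return SourceField(grid, values.reshape(grid.shape))
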