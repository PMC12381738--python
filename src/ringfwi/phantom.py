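"""Parametric numerical breast phantoms and frequency-domain data synthesis.

The phantom is an ellipsoidal breast (subcutaneous fat) in a water bath,
containing smooth fibroglandular blobs, spherical lesions, and an optional
skin shell. The piecewise-constant tissue map is blurred by a Gaussian of a
stated smoothing length and converted to slowness. All sound speeds sit in
the 1400-1600 m/s range typical of breast tissue; defaults are water 1500,
fat 1440, fibroglandular 1560, lesion 1580, skin 1600 m/s.

Observed channel data are synthesized directly in the frequency domain: for
every transmit and frequency the heterogeneous Helmholtz equation is solved
and sampled at the receiving elements. Circular complex Gaussian noise can
be added at a stated dB level relative to the mean signal power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi

from .acquisition import (
    RingArraySpec,
    SamplingOperator,
    TransmitSet,
    make_cylindrical_source,
)
from .grids import Grid, SlownessField
from .helmholtz import BornSeriesSettings, make_solver

__all__ = [
    "TissueBlob",
    "Lesion",
    "PhantomSpec",
    "FrequencyData",
    "generate_phantom",
    "simulate_observed_data",
    "add_noise",
]

log = logging.getLogger(__name__)

_TISSUE_SPEED_RANGE = (1300.0, 1700.0)


@dataclass(frozen=True)
class TissueBlob:
    """Smooth ellipsoidal fibroglandular region (meters, m/s)."""

    center: tuple
    radii: tuple
    speed_mps: float = 1560.0


@dataclass(frozen=True)
class Lesion:
    """Spherical lesion (meters, m/s)."""

    center: tuple
    radius: float
    speed_mps: float = 1580.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric breast phantom: geometry, tissue speeds, smoothing, seed."""

    breast_center: tuple = (0.0, 0.0, 0.0)
    breast_radii: tuple = (0.07, 0.07, 0.08)
    water_mps: float = 1500.0
    fat_mps: float = 1440.0
    fibroglandular: tuple = ()
    lesions: tuple = ()
    skin_thickness: float = 0.0
    skin_mps: float = 1600.0
    smoothing: float = 0.003
    seed: int = 0

    def __post_init__(self):
        speeds = [self.water_mps, self.fat_mps, self.skin_mps]
        speeds += [b.speed_mps for b in self.fibroglandular]
        speeds += [l.speed_mps for l in self.lesions]
        lo, hi = _TISSUE_SPEED_RANGE
        if any(not (lo <= c <= hi) for c in speeds):
            raise ValueError(f"all sound speeds must lie in [{lo}, {hi}] m/s")
        object.__setattr__(self, "fibroglandular", tuple(self.fibroglandular))
        object.__setattr__(self, "lesions", tuple(self.lesions))
        self._check_lesions_inside()

    def _check_lesions_inside(self):
        c = np.asarray(self.breast_center)
        a = np.asarray(self.breast_radii)
        ndim = len(a)
        for les in self.lesions:
            rho = np.linalg.norm((np.asarray(les.center)[:ndim] - c[:ndim]) / a)
            if rho + les.radius / a.min() > 1.0:
                raise ValueError(f"lesion at {les.center} extends outside the breast")

    @classmethod
    def random(
        cls,
        seed: int,
        ndim: int = 3,
        breast_radii=None,
        n_blobs: int = 3,
        n_lesions: int = 1,
        contrast_scale: float = 1.0,
        **kwargs,
    ) -> "PhantomSpec":
        """Reproducible phantom with randomly placed blobs and lesions.

        ``contrast_scale`` shrinks every tissue's deviation from water
        (useful for low-contrast test problems).
        """
        rng = np.random.default_rng(seed)
        if breast_radii is None:
            breast_radii = (0.07, 0.07, 0.08)[:ndim]
        a = np.asarray(breast_radii, float)
        water = kwargs.pop("water_mps", 1500.0)

        def scaled(c):
            return water + contrast_scale * (c - water)

        blobs = []
        for _ in range(n_blobs):
            center = rng.uniform(-0.45, 0.45, ndim) * a
            radii = rng.uniform(0.2, 0.4, ndim) * a
            blobs.append(TissueBlob(tuple(center), tuple(radii), scaled(1560.0)))
        lesions = []
        for _ in range(n_lesions):
            center = rng.uniform(-0.4, 0.4, ndim) * a
            radius = float(rng.uniform(0.08, 0.14) * a.min())
            lesions.append(Lesion(tuple(center), radius, scaled(1580.0)))
        return cls(
            breast_center=(0.0,) * ndim,
            breast_radii=tuple(a),
            water_mps=water,
            fat_mps=scaled(kwargs.pop("fat_mps", 1440.0)),
            fibroglandular=tuple(blobs),
            lesions=tuple(lesions),
            seed=seed,
            **kwargs,
        )


def generate_phantom(spec: PhantomSpec, grid: Grid) -> SlownessField:
    """Rasterize the tissue map on the grid, smooth it, convert to slowness."""
    coords = grid.meshgrid()
    ndim = grid.ndim
    c = np.asarray(spec.breast_center)[:ndim]
    a = np.asarray(spec.breast_radii)[:ndim]
    rho = np.sqrt(sum(((x - ci) / ai) ** 2 for x, ci, ai in zip(coords, c, a)))

    speed = np.full(grid.shape, spec.water_mps)
    speed[rho <= 1.0] = spec.fat_mps
    if spec.skin_thickness > 0:
        t = spec.skin_thickness / a.min()
        speed[(rho <= 1.0) & (rho >= 1.0 - t)] = spec.skin_mps
    for blob in spec.fibroglandular:
        bc = np.asarray(blob.center)[:ndim]
        br = np.asarray(blob.radii)[:ndim]
        r = np.sqrt(sum(((x - ci) / ri) ** 2 for x, ci, ri in zip(coords, bc, br)))
        speed[(r <= 1.0) & (rho <= 1.0)] = blob.speed_mps
    for les in spec.lesions:
        lc = np.asarray(les.center)[:ndim]
        r = np.sqrt(sum((x - ci) ** 2 for x, ci in zip(coords, lc)))
        speed[r <= les.radius] = les.speed_mps

    if spec.smoothing > 0:
        speed = ndi.gaussian_filter(speed, sigma=spec.smoothing / grid.h, mode="nearest")
    return SlownessField(grid, 1.0 / speed)


@dataclass(frozen=True)
class FrequencyData:
    """Complex receiver measurements per transmit, per frequency.

    ``data[f]`` has shape (n_transmits, n_elements) with element index
    row * n_elements_per_row + azimuth.
    """

    frequencies: tuple
    data: dict
    array_spec: RingArraySpec
    transmits: TransmitSet
    noise: dict | None = None

    def __post_init__(self):
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        n_tx = len(self.transmits)
        n_rx = self.array_spec.n_elements
        for f in freqs:
            mat = np.asarray(self.data[f], complex)
            if mat.shape != (n_tx, n_rx):
                raise ValueError(
                    f"data at {f:g} Hz has shape {mat.shape}, expected ({n_tx}, {n_rx})"
                )
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"data at {f:g} Hz contains non-finite values")
            self.data[f] = mat

    def matrix(self, frequency: float) -> np.ndarray:
        for f in self.frequencies:
            if np.isclose(f, frequency, rtol=1e-9):
                return self.data[f]
        raise KeyError(f"no data at {frequency:g} Hz (have {self.frequencies})")

    def row_subset(self, row: int) -> np.ndarray:
        """Stacked per-frequency matrices restricted to one receiver row."""
        n = self.array_spec.n_elements_per_row
        sl = slice(row * n, (row + 1) * n)
        return {f: self.data[f][:, sl] for f in self.frequencies}


def _refined(truth: SlownessField, factor: int) -> SlownessField:
    """Resample the slowness onto a ``factor`` x finer grid (linear interp)."""
    from scipy.interpolate import RegularGridInterpolator

    grid = truth.grid
    new_shape = tuple((n - 1) * factor + 1 for n in grid.shape)
    new_spacing = tuple(s / factor for s in grid.spacing)
    fine = Grid(new_shape, new_spacing, grid.origin)
    interp = RegularGridInterpolator(grid.axes(), truth.values, method="linear")
    pts = np.stack([c.ravel() for c in fine.meshgrid()], axis=-1)
    values = interp(pts).reshape(fine.shape)
    return SlownessField(fine, values)


def simulate_observed_data(
    truth: SlownessField,
    array_spec: RingArraySpec,
    transmits: TransmitSet,
    frequencies,
    settings: BornSeriesSettings,
    method: str = "born",
    stencil: str = "linear",
    supersample: int = 1,
) -> FrequencyData:
    """Synthesize noiseless frequency-domain channel data p = K u per transmit.

    ``supersample > 1`` solves on a finer simulation grid than the inversion
    grid (same element positions), mitigating the inverse crime; the
    resulting data difference is logged by the caller, not asserted.
    """
    transmits.validate_against(array_spec)
    sim_truth = _refined(truth, supersample) if supersample > 1 else truth
    grid = sim_truth.grid
    K = SamplingOperator.for_array(array_spec, grid, stencil)
    sources = np.stack(
        [make_cylindrical_source(array_spec, i, grid, stencil).values for i in transmits.indices]
    )
    data = {}
    for f in frequencies:
        omega = 2 * np.pi * float(f)
        solver = make_solver(sim_truth, omega, settings, method)
        u = solver.solve(sources)
        data[float(f)] = K.sample(u)
        log.info("simulated %d transmits at %.0f Hz", len(transmits), f)
    return FrequencyData(tuple(float(f) for f in frequencies), data, array_spec, transmits)


def add_noise(data: FrequencyData, level_db: float, seed: int) -> FrequencyData:
    """Add circular complex Gaussian noise at ``level_db`` below signal power.

    The noise power per entry is 10^(level_db/10) times the mean |signal|^2
    over every entry of every frequency (global convention); -20 dB therefore
    means a noise-to-signal power ratio of 0.01.
    """
    if level_db >= 0:
        raise ValueError("noise level must be negative dB (below signal power)")
    rng = np.random.default_rng(seed)
    signal_power = float(np.mean([np.mean(np.abs(m) ** 2) for m in data.data.values()]))
    sigma = np.sqrt(signal_power * 10.0 ** (level_db / 10.0) / 2.0)
    noisy = {}
    for f in data.frequencies:
        m = data.data[f]
        noisy[f] = m + sigma * (rng.standard_normal(m.shape) + 1j * rng.standard_normal(m.shape))
    return replace(
        data, data=noisy, noise={"level_db": float(level_db), "seed": int(seed)}
    )
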