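"""HDF5 containers for fields, volumes and channel data; YAML run configs.

Layouts
-------
Scalar fields (slowness, sound-speed volumes, Helmholtz solutions): dataset
``values`` with attributes ``spacing_m``, ``origin_m``, ``kind`` and, for
solutions, ``omega_rad_s``. All floats are stored as 64-bit; complex arrays
as separate real/imag datasets.

Channel data: one group per frequency named ``f_<hertz>`` holding datasets
``real`` and ``imag`` shaped (n_transmits, n_receivers); root attributes
carry the acquisition geometry, transmit indices and noise descriptor.
"""

from __future__ import annotations


import h5py
import numpy as np
import yaml

from .acquisition import RingArraySpec, TransmitSet
from .grids import Grid, HelmholtzSolution, SlownessField
from .helmholtz import BornSeriesSettings
from .fwi import FWIConfig
from .phantom import FrequencyData, PhantomSpec

__all__ = [
    "SchemaError",
    "save_field",
    "load_slowness",
    "save_volume",
    "load_volume",
    "save_frequency_data",
    "load_frequency_data",
    "load_run_config",
    "dump_run_config",
    "default_run_config",
]


class SchemaError(ValueError):
    """An HDF5 file does not follow the expected layout."""


def _require_attr(obj, name, path):
    if name not in obj.attrs:
        raise SchemaError(f"{path}: missing required attribute {name!r}")
    return obj.attrs[name]


def _write_grid_attrs(node, grid: Grid):
    node.attrs["spacing_m"] = np.asarray(grid.spacing, float)
    node.attrs["origin_m"] = np.asarray(grid.origin, float)


def _read_grid(node, path, shape):
    spacing = _require_attr(node, "spacing_m", path)
    origin = _require_attr(node, "origin_m", path)
    return Grid(tuple(shape), tuple(np.atleast_1d(spacing)), tuple(np.atleast_1d(origin)))


def save_field(path, field, kind=None):
    """Persist a SlownessField, HelmholtzSolution or sound-speed volume."""
    with h5py.File(path, "w") as f:
        if isinstance(field, HelmholtzSolution):
            f.create_dataset("values_real", data=field.values.real.astype(np.float64))
            f.create_dataset("values_imag", data=field.values.imag.astype(np.float64))
            f.attrs["omega_rad_s"] = float(field.omega)
            f.attrs["kind"] = "pressure"
            _write_grid_attrs(f, field.grid)
        else:
            values = field.values if isinstance(field, SlownessField) else np.asarray(field)
            f.create_dataset("values", data=np.asarray(values, np.float64))
            f.attrs["kind"] = kind or ("slowness" if isinstance(field, SlownessField) else "volume")
            grid = field.grid if isinstance(field, SlownessField) else None
            if grid is not None:
                _write_grid_attrs(f, grid)


def save_volume(path, values, grid: Grid, kind="sound_speed"):
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.asarray(values, np.float64))
        f.attrs["kind"] = kind
        _write_grid_attrs(f, grid)


def load_volume(path):
    """Read any real scalar volume; returns (values, grid, kind)."""
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise SchemaError(f"{path}: missing dataset 'values'")
        values = f["values"][...]
        grid = _read_grid(f, str(path), values.shape)
        kind = f.attrs.get("kind", "volume")
    return values, grid, str(kind)


def load_slowness(path) -> SlownessField:
    values, grid, kind = load_volume(path)
    if kind == "sound_speed":
        values = 1.0 / values
    return SlownessField(grid, values)


def save_frequency_data(path, data: FrequencyData):
    with h5py.File(path, "w") as f:
        spec = data.array_spec
        f.attrs["frequencies_hz"] = np.asarray(data.frequencies, float)
        f.attrs["radius_m"] = spec.radius
        f.attrs["n_rows"] = spec.n_rows
        f.attrs["n_elements_per_row"] = spec.n_elements_per_row
        f.attrs["row_pitch_m"] = spec.row_pitch
        f.attrs["center_m"] = np.asarray(spec.center, float)
        f.attrs["transmit_indices"] = np.asarray(data.transmits.indices, int)
        if data.noise is not None:
            f.attrs["noise_level_db"] = data.noise["level_db"]
            f.attrs["noise_seed"] = data.noise["seed"]
        for freq in data.frequencies:
            g = f.create_group(f"f_{int(round(freq))}")
            m = data.data[freq]
            g.create_dataset("real", data=m.real.astype(np.float64))
            g.create_dataset("imag", data=m.imag.astype(np.float64))


def load_frequency_data(path) -> FrequencyData:
    with h5py.File(path, "r") as f:
        freqs = tuple(float(x) for x in _require_attr(f, "frequencies_hz", str(path)))
        spec = RingArraySpec(
            radius=float(_require_attr(f, "radius_m", str(path))),
            n_rows=int(_require_attr(f, "n_rows", str(path))),
            n_elements_per_row=int(_require_attr(f, "n_elements_per_row", str(path))),
            row_pitch=float(_require_attr(f, "row_pitch_m", str(path))),
            center=tuple(_require_attr(f, "center_m", str(path))),
        )
        transmits = TransmitSet(tuple(int(i) for i in _require_attr(f, "transmit_indices", str(path))))
        noise = None
        if "noise_level_db" in f.attrs:
            noise = {
                "level_db": float(f.attrs["noise_level_db"]),
                "seed": int(f.attrs["noise_seed"]),
            }
        data = {}
        for freq in freqs:
            name = f"f_{int(round(freq))}"
            if name not in f:
                raise SchemaError(f"{path}: missing group {name!r}")
            g = f[name]
            for ds in ("real", "imag"):
                if ds not in g:
                    raise SchemaError(f"{path}/{name}: missing dataset {ds!r}")
            data[freq] = g["real"][...] + 1j * g["imag"][...]
    return FrequencyData(freqs, data, spec, transmits, noise)


# ---------------------------------------------------------------------------
# YAML run configuration


def default_run_config() -> dict:
    """Full default configuration, suitable for echoing to YAML."""
    solver = BornSeriesSettings()
    fwi = FWIConfig()
    return {
        "grid": {"shape": [64, 64, 64], "spacing_m": 0.0025, "origin": "centered"},
        "geometry": {
            "radius_m": RingArraySpec.radius,
            "n_rows": RingArraySpec.n_rows,
            "n_elements_per_row": RingArraySpec.n_elements_per_row,
            "row_pitch_m": RingArraySpec.row_pitch,
            "transmit_indices": "all",
        },
        "phantom": {
            "breast_radii_m": [0.07, 0.07, 0.08],
            "water_mps": 1500.0,
            "fat_mps": 1440.0,
            "n_blobs": 3,
            "n_lesions": 1,
            "smoothing_m": 0.003,
            "seed": 0,
        },
        "noise": {"level_db": -20.0, "seed": 0},
        "solver": {
            "tolerance": solver.tolerance,
            "max_iterations": solver.max_iterations,
            "pad_width": solver.pad_width,
            "absorption_strength": solver.absorption_strength,
            "dtype": solver.dtype,
        },
        "fwi": {
            "frequencies_hz": list(fwi.frequencies),
            "iterations_per_frequency": fwi.iterations_per_frequency,
            "starting_speed_mps": fwi.starting_speed,
            "mode": fwi.mode,
            "max_speed_change_per_step_mps": fwi.max_speed_change_per_step,
        },
    }


def _merge(defaults, override):
    out = dict(defaults)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_run_config(path) -> dict:
    """Read a YAML run config, merged over the full defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_run_config(), user)


def dump_run_config(path, config=None):
    """Write a config (defaults merged in) so every knob is echoed."""
    merged = _merge(default_run_config(), config or {})
    with open(path, "w") as fh:
        yaml.safe_dump(merged, fh, sort_keys=False)
    return merged


def build_objects(config: dict):
    """Instantiate (grid, array_spec, transmits, solver_settings, fwi_config)."""
    gc = config["grid"]
    shape = tuple(int(n) for n in gc["shape"])
    spacing = float(gc["spacing_m"])
    if gc.get("origin", "centered") == "centered":
        grid = Grid.centered(shape, spacing)
    else:
        grid = Grid(shape, (spacing,) * len(shape), tuple(gc["origin"]))
    ac = config["geometry"]
    spec = RingArraySpec(
        radius=float(ac["radius_m"]),
        n_rows=int(ac["n_rows"]),
        n_elements_per_row=int(ac["n_elements_per_row"]),
        row_pitch=float(ac["row_pitch_m"]),
    )
    ti = ac.get("transmit_indices", "all")
    transmits = (
        TransmitSet.every(spec) if ti == "all" else TransmitSet(tuple(int(i) for i in ti))
    )
    sc = config["solver"]
    solver = BornSeriesSettings(
        tolerance=float(sc["tolerance"]),
        max_iterations=int(sc["max_iterations"]),
        pad_width=None if sc.get("pad_width") is None else int(sc["pad_width"]),
        absorption_strength=float(sc["absorption_strength"]),
        dtype=str(sc.get("dtype", "complex128")),
    )
    fc = config["fwi"]
    fwi_config = FWIConfig(
        frequencies=tuple(float(f) for f in fc["frequencies_hz"]),
        iterations_per_frequency=int(fc["iterations_per_frequency"]),
        starting_speed=float(fc["starting_speed_mps"]),
        mode=str(fc.get("mode", "3d")),
        solver=solver,
        max_speed_change_per_step=float(fc.get("max_speed_change_per_step_mps", 10.0)),
    )
    return grid, spec, transmits, solver, fwi_config


def phantom_spec_from_config(config: dict) -> PhantomSpec:
    pc = config["phantom"]
    ndim = len(config["grid"]["shape"])
    return PhantomSpec.random(
        seed=int(pc.get("seed", 0)),
        ndim=ndim,
        breast_radii=tuple(float(r) for r in pc["breast_radii_m"])[:ndim],
        n_blobs=int(pc.get("n_blobs", 3)),
        n_lesions=int(pc.get("n_lesions", 1)),
        water_mps=float(pc.get("water_mps", 1500.0)),
        fat_mps=float(pc.get("fat_mps", 1440.0)),
        smoothing=float(pc.get("smoothing_m", 0.003)),
    )
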