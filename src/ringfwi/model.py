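"""Model/results interface to the waveform inversion.

:class:`WaveformInversion` is constructed from observed channel data and an
inversion grid; ``fit()`` runs the multi-frequency reconstruction and
returns a :class:`WaveformInversionResults` carrying the sound-speed volume,
the per-frequency cost history, and evaluation/plotting helpers.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .fwi import FWIConfig, FWIResult, run_fwi, run_slicewise_fwi
from .grids import Grid, SlownessField
from .metrics import EvaluationReport, evaluate
from .phantom import FrequencyData

__all__ = ["WaveformInversion", "WaveformInversionResults"]


class WaveformInversion:
    """Frequency-domain FWI model for ring-array channel data.

    Parameters
    ----------
    data
        Observed complex channel data per transmit and frequency.
    grid
        Inversion grid (3D volume, or 2D for single-row data).
    config
        Schedule, starting model and solver settings; defaults to the
        standard 200-800 kHz / 5-iteration protocol.
    """

    def __init__(self, data: FrequencyData, grid: Grid, config: Optional[FWIConfig] = None):
        self.data = data
        self.grid = grid
        self.config = config if config is not None else FWIConfig()

    @classmethod
    def from_hdf5(cls, path, grid: Grid, config: Optional[FWIConfig] = None):
        from .io import load_frequency_data

        return cls(load_frequency_data(path), grid, config)

    def fit(self, mode: Optional[str] = None) -> "WaveformInversionResults":
        """Run the inversion; ``mode`` overrides the config ('3d'/'slicewise')."""
        config = self.config if mode is None else replace(self.config, mode=mode)
        runner = run_slicewise_fwi if config.mode == "slicewise" else run_fwi
        result = runner(self.data, self.grid, config)
        return WaveformInversionResults(self, result)


class WaveformInversionResults:
    """Reconstruction, cost history and diagnostics of one inversion run."""

    def __init__(self, model: WaveformInversion, result: FWIResult):
        self.model = model
        self._result = result

    @property
    def sound_speed(self) -> np.ndarray:
        """Reconstructed sound speed, m/s, on the inversion grid."""
        return self._result.sound_speed

    @property
    def slowness(self) -> SlownessField:
        return SlownessField(self.grid, self._result.slowness)

    @property
    def grid(self) -> Grid:
        return self._result.grid

    @property
    def mode(self) -> str:
        return self._result.mode

    @property
    def cost_history(self) -> dict:
        return self._result.cost_history

    @property
    def flags(self) -> dict:
        return self._result.flags

    def evaluate(self, truth, mask=None) -> EvaluationReport:
        """RMSE (m/s) and Pearson correlation against a true volume."""
        truth_values = truth.sound_speed if isinstance(truth, SlownessField) else np.asarray(truth)
        return evaluate(self.sound_speed, truth_values, mask)

    def save(self, path):
        from .io import save_volume

        save_volume(path, self.sound_speed, self.grid)

    def summary(self) -> str:
        """Plain-text run summary in the spirit of a fit report."""
        r = self._result
        lines = [
            "Waveform inversion results",
            "=" * 54,
            f"mode:            {r.mode}",
            f"grid:            {'x'.join(map(str, r.grid.shape))} @ {r.grid.h * 1e3:.3g} mm",
            f"frequencies:     {len(r.config.frequencies)} "
            f"({r.config.frequencies[0] / 1e3:.0f}-{r.config.frequencies[-1] / 1e3:.0f} kHz)",
            f"iterations/freq: {r.config.iterations_per_frequency}",
            f"speed range:     {self.sound_speed.min():.1f} - {self.sound_speed.max():.1f} m/s",
            "-" * 54,
        ]
        hist = r.cost_history
        if r.mode == "slicewise":
            lines.append(f"slices inverted: {len(hist)} (failed: {len(r.flags.get('failed_rows', []))})")
            # average cost reduction across slices per frequency
            freqs = r.config.frequencies
            for f in freqs:
                ratios = [h[f][-1] / h[f][0] for h in hist.values() if h[f][0] > 0]
                if ratios:
                    lines.append(f"  {f / 1e3:6.0f} kHz  mean final/initial cost {np.mean(ratios):.3g}")
        else:
            lines.append(f"{'freq (kHz)':>10}  {'initial cost':>13}  {'final cost':>13}")
            for f, costs in hist.items():
                lines.append(f"{f / 1e3:10.0f}  {costs[0]:13.5g}  {costs[-1]:13.5g}")
        return "\n".join(lines)

    def plot_slices(self, path=None, vmin=1400.0, vmax=1600.0):
        """Orthogonal mid-plane slices of the reconstruction (grayscale)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vol = self.sound_speed
        if vol.ndim == 2:
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(vol.T, cmap="gray", vmin=vmin, vmax=vmax, origin="lower")
            ax.set_title("sound speed (m/s)")
        else:
            fig, axes = plt.subplots(1, 3, figsize=(11, 4))
            mids = [n // 2 for n in vol.shape]
            views = [vol[mids[0], :, :], vol[:, mids[1], :], vol[:, :, mids[2]]]
            for ax, view, name in zip(axes, views, ["sagittal", "coronal", "axial"]):
                ax.imshow(view.T, cmap="gray", vmin=vmin, vmax=vmax, origin="lower")
                ax.set_title(name)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
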