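"""Reconstruction quality metrics: RMSE (m/s) and Pearson correlation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["EvaluationReport", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    """RMSE and PCC of a reconstruction against ground truth over a mask."""

    rmse: float
    pcc: float
    n_voxels: int
    mask: str = "whole volume"

    def __post_init__(self):
        if self.rmse < 0 or not -1.0 <= self.pcc <= 1.0 + 1e-12:
            raise ValueError("invalid metric values")

    def as_dict(self) -> dict:
        return {
            "rmse_mps": self.rmse,
            "pcc": self.pcc,
            "n_voxels": self.n_voxels,
            "mask": self.mask,
        }


def evaluate(recon, truth, mask: Optional[np.ndarray] = None, mask_name=None) -> EvaluationReport:
    """RMSE = sqrt(mean (recon - truth)^2) and Pearson r over the masked voxels.

    Raises if either masked set is constant (correlation undefined).
    """
    recon = np.asarray(recon, float)
    truth = np.asarray(truth, float)
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch: {recon.shape} vs {truth.shape}")
    if mask is not None:
        sel = np.asarray(mask, bool)
        if sel.shape != recon.shape:
            raise ValueError("mask shape does not match volumes")
        if not sel.any():
            raise ValueError("mask selects no voxels")
        a, b = recon[sel], truth[sel]
        name = mask_name or "masked region"
    else:
        a, b = recon.ravel(), truth.ravel()
        name = mask_name or "whole volume"
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant values over the mask: correlation undefined")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    pcc = float(stats.pearsonr(a, b).statistic)
    return EvaluationReport(rmse=rmse, pcc=min(pcc, 1.0), n_voxels=a.size, mask=name)
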