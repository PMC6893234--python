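"""Seed-based functional connectivity: whole-volume Pearson r, Fisher z.

Runs entering these maps must already be denoised (confound-regressed and
band-passed); the seed time course is the unweighted mean over seed voxels.
Correlations are clipped to 1 - 1e-7 in magnitude before atanh so perfect
self-correlation maps to a large finite z instead of infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import BoldRun, SpatialGrid, VolumeMask, check_same_grid

_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMap:
    """Voxelwise Fisher-z map for one seed (NaN at zero-variance voxels)."""

    grid: SpatialGrid
    values: np.ndarray
    seed_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValidationError("map shape does not match grid")


def seed_timecourse(run: BoldRun, seed: VolumeMask) -> np.ndarray:
    """Unweighted mean over seed voxels at each time point."""
    check_same_grid(run, seed)
    if seed.n_voxels == 0:
        raise ValidationError("seed mask is empty")
    return run.data[seed.voxels].mean(axis=0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def fc_map(
    run: BoldRun, seed_tc: np.ndarray, seed_label: str = ""
) -> ConnectivityMap:
    """Pearson r of every voxel against the seed time course, Fisher
    transformed."""
    seed_tc = np.asarray(seed_tc, dtype=float)
    if seed_tc.shape[0] != run.n_volumes:
        raise ValidationError("seed time course length does not match run")
    s = seed_tc - seed_tc.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValidationError("seed time course has zero variance")
    Y = run.data.reshape(-1, run.n_volumes)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ s) / (y_norm * s_norm)
    r[y_norm == 0] = np.nan
    z = np.where(np.isnan(r), np.nan, fisher_z(np.nan_to_num(r)))
    return ConnectivityMap(run.grid, z.reshape(run.grid.shape), seed_label)


def roi_fc(
    maps: dict,
    target_roi: VolumeMask,
) -> pd.DataFrame:
    """Mean Fisher z within a target ROI per (subject, condition) map."""
    rows = []
    for (subject, condition), cmap in maps.items():
        check_same_grid(cmap, target_roi)
        vals = cmap.values[target_roi.voxels]
        if np.isnan(vals).all():
            raise ValidationError(
                f"all target-ROI voxels are NaN for ({subject}, {condition})"
            )
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "seed": cmap.seed_label,
                "mean_z": float(np.nanmean(vals)),
            }
        )
    return pd.DataFrame(rows)
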