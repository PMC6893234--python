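"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF is the share of a voxel's spectral *amplitude* (square root of power)
lying in a low-frequency band, relative to the whole positive-frequency
range up to Nyquist.  The series is linearly detrended but never band-pass
filtered before the transform.  Frequency bins are the natural DFT bins
f_k = k / (N * TR), and the band edges are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend

from .exceptions import ValidationError
from .io import BoldRun, SpatialGrid, VolumeMask, check_same_grid


def nyquist(tr_seconds: float) -> float:
    """Upper bound of the sampled frequency range: 1 / (2 * TR)."""
    if not tr_seconds > 0:
        raise ValidationError(f"tr_seconds must be > 0, got {tr_seconds}")
    return 1.0 / (2.0 * tr_seconds)


@dataclass(frozen=True)
class FrequencyBand:
    """A positive frequency band in Hz; the default is the 0.008-0.09 Hz
    low-frequency band conventional for resting-state BOLD."""

    low_hz: float = 0.008
    high_hz: float = 0.09

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError(
                f"need 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )

    def validate_against_tr(self, tr_seconds: float) -> None:
        ny = nyquist(tr_seconds)
        if self.high_hz > ny + 1e-12:
            raise ValidationError(
                f"band upper edge {self.high_hz} Hz exceeds Nyquist {ny} Hz "
                f"for TR {tr_seconds} s"
            )


@dataclass
class FalffMap:
    """Voxelwise fALFF values on a grid (NaN where the spectrum is empty)."""

    grid: SpatialGrid
    values: np.ndarray
    band: FrequencyBand
    tr_seconds: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValidationError("fALFF values do not match the grid shape")


def falff_series(x: np.ndarray, tr_seconds: float, band: FrequencyBand) -> np.ndarray:
    """fALFF of 1D series (or a stack of series along the last axis).

    Detrend -> DFT -> amplitude = |X_k| at each positive bin -> in-band sum
    over low <= f_k <= high divided by the sum over 0 < f_k <= Nyquist.
    Zero-variance series yield NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    band.validate_against_tr(tr_seconds)
    resid = detrend(x, axis=-1, type="linear")
    amp = np.abs(np.fft.rfft(resid, axis=-1))
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    positive = freqs > 1e-15
    in_band = positive & (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    num = amp[..., in_band].sum(axis=-1)
    den = amp[..., positive].sum(axis=-1)
    # zero-variance guard: a constant (or perfectly linear) series leaves
    # only rounding noise after detrending
    tiny = 1e-10 * np.maximum(1.0, np.abs(x).max(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > tiny, num / den, np.nan)
    return out


def compute_falff(run: BoldRun, band: FrequencyBand | None = None) -> FalffMap:
    """Voxelwise fALFF map of a (possibly smoothed, never band-passed) run."""
    if band is None:
        band = FrequencyBand()
    values = falff_series(run.data, run.tr_seconds, band)
    return FalffMap(run.grid, values, band, run.tr_seconds)


def extract_roi_mean(falff_map: FalffMap, roi: VolumeMask) -> float:
    """NaN-ignoring mean of the map over the ROI voxels."""
    check_same_grid(falff_map, roi)
    if roi.n_voxels == 0:
        raise ValidationError("ROI is empty")
    vals = falff_map.values[roi.voxels]
    n_nan = int(np.isnan(vals).sum())
    if n_nan == vals.size:
        raise ValidationError("all ROI voxels are NaN")
    if n_nan:
        warnings.warn(f"ignoring {n_nan} NaN voxel(s) in ROI mean")
    return float(np.nanmean(vals))


def zscore_across_subjects(values) -> np.ndarray:
    """(v - mean) / sd with sample sd (ddof=1) over the reference set.

    The reference set is all sessions entering one second-level model
    (pooled groups for the trait analysis; the three meditator conditions
    for state analyses).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise ValidationError(f"need at least 3 values to z-score, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero variance: cannot z-score")
    return (v - v.mean()) / sd


def roi_table(
    falff_maps: dict,
    rois: dict[str, VolumeMask],
) -> pd.DataFrame:
    """Long table of ROI-mean fALFF per session.

    ``falff_maps`` maps (subject, condition) -> FalffMap; ``rois`` maps
    roi name -> mask.  z-scores are added separately (see
    :func:`add_zscores`) because the reference set depends on the analysis.
    """
    rows = []
    for (subject, condition), fmap in falff_maps.items():
        for roi_name, roi in rois.items():
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "roi": roi_name,
                    "mean_falff": extract_roi_mean(fmap, roi),
                }
            )
    return pd.DataFrame(rows)


def add_zscores(table: pd.DataFrame, value_col: str = "mean_falff") -> pd.DataFrame:
    """z-score each ROI's values across all sessions present in the table."""
    out = table.copy()
    out["z"] = np.nan
    for _, idx in out.groupby("roi").groups.items():
        out.loc[idx, "z"] = zscore_across_subjects(out.loc[idx, value_col].values)
    return out
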