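"""Temporal denoising: outlier volumes, aCompCor confounds, regression.

The denoising model follows the anatomical-CompCor approach: principal
component time courses from eroded white-matter and CSF masks (extracted
from *unsmoothed* data), six motion parameters with their first-order
backward differences, one indicator regressor per outlier volume, and a
linear trend.  Global signal regression is deliberately excluded: it
artificially induces negative correlations and would confound the
interpretation of network anticorrelation.

Filtering order: the band-pass is applied simultaneously to the voxel data
and to every confound column, then each voxel is residualized on the
filtered confounds by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import detrend

from ._filters import bandpass_ideal
from .exceptions import ValidationError
from .falff import FrequencyBand
from .io import BoldRun, VolumeMask, check_same_grid


@dataclass(frozen=True)
class OutlierConfig:
    """Thresholds for the two artifact-detection rules: frame-to-frame
    translation (mm) and global-intensity deviation (SD units)."""

    displacement_mm: float = 0.5
    intensity_sd: float = 3.0

    def __post_init__(self):
        if self.displacement_mm <= 0 or self.intensity_sd <= 0:
            raise ValidationError("outlier thresholds must be > 0")


def global_signal(run: BoldRun, mask: VolumeMask | None = None) -> np.ndarray:
    """Mean image intensity per volume (over a mask if given)."""
    if mask is None:
        return run.data.reshape(-1, run.n_volumes).mean(axis=0)
    check_same_grid(run, mask)
    return run.data[mask.voxels].mean(axis=0)


def detect_outliers(
    motion, signal: np.ndarray, config: OutlierConfig | None = None
) -> np.ndarray:
    """Flag volumes by displacement (>0.5 mm step in x, y, or z from the
    previous frame; volume 0 exempt) or global intensity (>3 SD from the
    run mean).  SD is taken over the entire series (population SD)."""
    if config is None:
        config = OutlierConfig()
    motion = np.asarray(motion, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if motion.ndim != 2 or motion.shape[1] < 3:
        raise ValidationError("motion must be a time x 6 (or >=3) array")
    if motion.shape[0] != signal.shape[0]:
        raise ValidationError(
            f"motion rows ({motion.shape[0]}) != signal length ({signal.shape[0]})"
        )
    flags = np.zeros(signal.shape[0], dtype=bool)
    step = np.abs(np.diff(motion[:, :3], axis=0))
    flags[1:] = (step > config.displacement_mm).any(axis=1)
    sd = signal.std()
    if sd > 0:
        flags |= np.abs(signal - signal.mean()) > config.intensity_sd * sd
    return flags


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def erode_mask(mask: VolumeMask) -> VolumeMask:
    """One-voxel erosion: a voxel survives iff it and its 6 face neighbors
    are all inside the mask.  May return an empty mask (warning)."""
    if mask.n_voxels == 0:
        raise ValidationError("cannot erode an empty mask")
    eroded = ndimage.binary_erosion(
        mask.voxels, structure=_FACE_STRUCTURE, border_value=0
    )
    if not eroded.any():
        warnings.warn("erosion left an empty mask")
    return VolumeMask(mask.grid, eroded)


def acompcor_components(
    run: BoldRun, noise_mask: VolumeMask, n_components: int = 5
) -> np.ndarray:
    """Top principal-component time courses of the voxel x time matrix
    inside a (pre-eroded) noise mask.

    Per-voxel linear detrend and variance normalization precede the PCA;
    the run must be unsmoothed to avoid gray-matter contamination.
    Returns a time x k matrix with orthonormal columns.
    """
    check_same_grid(run, noise_mask)
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    X = run.data[noise_mask.voxels]  # voxels x time
    if X.shape[0] == 0:
        raise ValidationError("noise mask is empty")
    X = detrend(X, axis=1, type="linear")
    sd = X.std(axis=1)
    keep = sd > 0
    X = X[keep] / sd[keep, None]
    n_avail = min(X.shape[0], X.shape[1])
    if n_components > n_avail:
        warnings.warn(
            f"only {n_avail} component(s) available; requested {n_components}"
        )
        n_components = n_avail
    u, s, _ = np.linalg.svd(X.T, full_matrices=False)
    comps = u[:, :n_components].copy()
    # deterministic sign: largest-magnitude loading positive
    for k in range(comps.shape[1]):
        j = np.argmax(np.abs(comps[:, k]))
        if comps[j, k] < 0:
            comps[:, k] *= -1
    return comps


@dataclass
class ConfoundMatrix:
    """time x regressor nuisance matrix with per-column labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("confound matrix must be 2D")
        if self.values.shape[1] != len(self.labels):
            raise ValidationError("label count does not match column count")
        if not np.isfinite(self.values).all():
            raise ValidationError("confound matrix contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


def build_confounds(
    run: BoldRun,
    wm_mask: VolumeMask,
    csf_mask: VolumeMask,
    motion,
    outlier_flags: np.ndarray,
    n_components: int = 5,
) -> ConfoundMatrix:
    """Assemble WM + CSF aCompCor components, motion, motion derivatives,
    per-outlier indicators, and a linear trend.

    Masks are expected to be eroded already; components must come from the
    unsmoothed run.  All-zero columns (e.g. derivatives of constant motion)
    are dropped with a warning.
    """
    n = run.n_volumes
    motion = np.asarray(motion, dtype=float)
    flags = np.asarray(outlier_flags, dtype=bool)
    if motion.shape[0] != n or flags.shape[0] != n:
        raise ValidationError("motion/outlier length does not match run length")
    if flags.all():
        raise ValidationError("no usable volumes: every volume is flagged")

    cols, labels = [], []
    for tissue, mask in (("WM", wm_mask), ("CSF", csf_mask)):
        comps = acompcor_components(run, mask, n_components)
        for k in range(comps.shape[1]):
            cols.append(comps[:, k])
            labels.append(f"component_{k + 1}_{tissue}")
    for k in range(6):
        cols.append(motion[:, k])
        labels.append(f"motion_{k + 1}")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    for k in range(6):
        cols.append(deriv[:, k])
        labels.append(f"dmotion_{k + 1}")
    for t in np.nonzero(flags)[0]:
        ind = np.zeros(n)
        ind[t] = 1.0
        cols.append(ind)
        labels.append(f"outlier_{t}")
    cols.append(np.linspace(-0.5, 0.5, n))
    labels.append("trend")

    values = np.column_stack(cols)
    zero = (values == 0).all(axis=0)
    if zero.any():
        dropped = [lbl for lbl, z in zip(labels, zero) if z]
        warnings.warn(f"dropping all-zero confound column(s): {dropped}")
        values = values[:, ~zero]
        labels = [lbl for lbl, z in zip(labels, zero) if not z]
    return ConfoundMatrix(values, labels)


def denoise(
    run: BoldRun,
    confounds: ConfoundMatrix | None,
    band: FrequencyBand | None = None,
) -> BoldRun:
    """Regress filtered confounds out of (filtered) voxel time series.

    With ``band`` given, the ideal band-pass is applied to both the data
    and every confound column before the regression (residuals are then
    orthogonal to the *filtered* confounds).  With ``band=None`` no filter
    is applied and an intercept is added, so outlier-indicator regressors
    zero their volumes exactly.
    """
    Y = run.data.reshape(-1, run.n_volumes).T  # time x voxels
    if confounds is not None and confounds.n_timepoints != run.n_volumes:
        raise ValidationError("confound rows do not match run length")

    if band is not None:
        band.validate_against_tr(run.tr_seconds)
        Y = bandpass_ideal(Y, run.tr_seconds, band.low_hz, band.high_hz, axis=0)

    if confounds is not None and confounds.values.shape[1] > 0:
        X = confounds.values
        if band is not None:
            X = bandpass_ideal(X, run.tr_seconds, band.low_hz, band.high_hz, axis=0)
        else:
            X = np.column_stack([np.ones(run.n_volumes), X])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"confound matrix is rank deficient ({rank}/{X.shape[1]}); "
                "collinear columns resolved by least squares"
            )
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ beta

    data = Y.T.reshape(run.data.shape)
    return run.with_data(data)


def smooth(run: BoldRun, fwhm_mm: float = 8.0) -> BoldRun:
    """Gaussian spatial smoothing (sigma = FWHM / sqrt(8 ln 2)) per volume.

    Applied to runs entering fALFF and FC maps, never to tissue-mask
    extraction.
    """
    if fwhm_mm <= 0:
        return run
    sigma_vox = (fwhm_mm / np.sqrt(8.0 * np.log(2.0))) / run.grid.voxel_sizes_mm
    data = ndimage.gaussian_filter(run.data, sigma=tuple(sigma_vox) + (0.0,))
    return run.with_data(data)
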