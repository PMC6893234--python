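"""Shared DFT ideal band-pass filter.

One implementation serves both the synthetic generator (shaping latent
network signals) and the denoising stage (simultaneous filtering of data and
nuisance regressors), so spectral conventions cannot drift apart.
"""

from __future__ import annotations

import numpy as np


def bandpass_ideal(
    x: np.ndarray,
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    axis: int = -1,
) -> np.ndarray:
    """Zero all DFT bins outside [low_hz, high_hz] (inclusive edges).

    The DC bin is retained only if ``low_hz <= 0``; the output is therefore
    zero-mean for any positive low edge.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[axis]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = keep.size
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)
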