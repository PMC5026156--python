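"""Canonical haemodynamic response function and regressor construction.

The canonical HRF is the standard double-gamma impulse response (peak
delay 6 s, undershoot delay 16 s, unit dispersions, peak-to-undershoot
ratio 6) without temporal derivatives, peak-normalised so a unit-amplitude
sustained response plateaus near the stimulus amplitude.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InputError


def canonical_hrf(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on [0, duration_s) at fs Hz.

    The kernel is peak-normalised (max value 1) and starts at exactly 0
    at t = 0; its maximum falls near t = 5 s and it has a single late
    negative undershoot lobe.
    """
    if fs <= 0:
        raise ConfigurationError("sampling rate must be positive")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    kernel = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return kernel / kernel.max()


def _unit_gain(kernel: np.ndarray) -> np.ndarray:
    # Normalise to unit DC gain so a sustained block response plateaus at
    # the stimulus amplitude; the beta weight is then directly the peak
    # concentration change rather than an arbitrary convolution scale.
    return kernel / kernel.sum()


def block_regressor(onsets, block_duration_s: float, n_samples: int, fs: float,
                    kernel: np.ndarray) -> np.ndarray:
    """Boxcar at the given onsets convolved with the unit-gain ``kernel``."""
    box = np.zeros(n_samples)
    for onset in onsets:
        i0 = int(round(onset * fs))
        if not 0 <= i0 < n_samples:
            raise InputError(f"block onset {onset} s lies outside the recording")
        i1 = min(int(round((onset + block_duration_s) * fs)), n_samples)
        box[i0:i1] = 1.0
    return np.convolve(box, _unit_gain(kernel))[:n_samples]


def impulse_regressor(onsets, n_samples: int, fs: float, kernel: np.ndarray) -> np.ndarray:
    """Delta functions at the given onsets convolved with the unit-gain kernel."""
    imp = np.zeros(n_samples)
    for onset in onsets:
        i0 = int(round(onset * fs))
        if not 0 <= i0 < n_samples:
            raise InputError(f"event onset {onset} s lies outside the recording")
        imp[i0] += 1.0
    return np.convolve(imp, _unit_gain(kernel))[:n_samples]
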