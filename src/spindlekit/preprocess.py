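"""Signal conditioning: line-noise notches, zero-phase bandpass, CAR.

All filters are applied forward-backward (zero phase), because the phase
analyses downstream (instantaneous phase of the 9-18 Hz band) cannot tolerate
group delay.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import ParameterError
from .recording import Recording

__all__ = ["remove_line_noise", "bandpass", "common_average_reference", "zscore"]

#: highest harmonic considered for notching, Hz (the analysis band ends at 100)
_HARMONIC_CEILING = 100.0


def remove_line_noise(rec: Recording, line_freq: float, q: float = 35.0) -> Recording:
    """Zero-phase IIR notches at ``line_freq`` and harmonics below min(fs/2, 100 Hz).

    Narrow notches (quality factor ``q``) leave the 9-18 Hz spindle band
    essentially untouched while attenuating mains power by well over 20 dB.
    """
    if not 0 < line_freq < rec.fs / 2:
        raise ParameterError(f"line_freq {line_freq} must lie in (0, fs/2={rec.fs / 2})")
    out = rec.data
    ceiling = min(rec.fs / 2, _HARMONIC_CEILING)
    freq = line_freq
    while freq < ceiling * (1 - 1e-9):
        b, a = signal.iirnotch(freq, q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=-1)
        freq += line_freq
    return rec.with_data(out)


def bandpass(rec: Recording, lo: float, hi: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass on every channel."""
    if not 0 < lo < hi < rec.fs / 2:
        raise ParameterError(
            f"band ({lo}, {hi}) must satisfy 0 < lo < hi < fs/2 = {rec.fs / 2}"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=-1))


def bandpass_array(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """`bandpass` for bare arrays (last axis is time)."""
    if not 0 < lo < hi < fs / 2:
        raise ParameterError(f"band ({lo}, {hi}) must satisfy 0 < lo < hi < fs/2 = {fs / 2}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ParameterError("common average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def zscore(rec: Recording) -> Recording:
    """Per-channel z-score (display/export helper; detectors normalise per window)."""
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return rec.with_data((rec.data - mu) / sd)
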