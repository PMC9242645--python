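"""Amplitude-thresholding (AT) baseline detector.

The classic approach the CNN is compared against: bandpass at 11-15 Hz, take
the Hilbert envelope, and call a 500 ms window positive when the envelope
stays above a predetermined threshold throughout the window. Positive windows
are merged with the same rule as the CNN; events longer than 3 s are
discarded. The threshold is either calibrated per electrode to a target rate
(~2 events/min) and averaged across electrodes, or a fixed multiple of the
envelope standard deviation (3 SD). Because the cutoff is predetermined
rather than adaptive, AT preferentially selects the largest-amplitude events
-- the weakness the SNR/CNN pipeline is designed to remove.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import CalibrationError, ParameterError
from .preprocess import bandpass_array
from .recording import Recording, SpindleEvent
from .windows import merge_windows, slice_windows, window_starts

__all__ = ["ATConfig", "envelope", "sd_threshold", "calibrate_threshold", "at_detect"]


@dataclass
class ATConfig:
    band: tuple[float, float] = (11.0, 15.0)
    window: float = 0.5
    stride: float = 0.1
    max_dur: float = 3.0
    threshold_mode: str = "rate_calibrated"   # or "sd_multiple"
    target_rate: float = 2.0                  # events per minute
    sd_k: float = 3.0
    edge_exclude: float = 0.25                # s excluded from envelope statistics

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ParameterError("target_rate must be positive")


def envelope(rec: Recording, band: tuple[float, float] = (11.0, 15.0)) -> np.ndarray:
    """Instantaneous amplitude: |analytic signal| of the band-passed trace.

    Shape (n_channels, n_samples); non-negative; length preserved.
    """
    bp = bandpass_array(rec.data, rec.fs, band[0], band[1])
    n = rec.n_samples
    nfft = int(2 ** np.ceil(np.log2(max(n, 2))))   # pad to power of two for speed
    return np.abs(hilbert(bp, N=nfft, axis=-1)[..., :n])


def _interior(env: np.ndarray, fs: float, edge: float) -> np.ndarray:
    k = int(round(edge * fs))
    return env[..., k : env.shape[-1] - k] if k > 0 and env.shape[-1] > 2 * k else env


def sd_threshold(rec: Recording, cfg: ATConfig = ATConfig()) -> float:
    """SD-multiple threshold: ``sd_k`` standard deviations of the envelope.

    Computed per channel over the envelope interior (first/last 250 ms
    excluded for Hilbert edge effects) and averaged across channels. The
    value is meant to be *predetermined* -- estimated once on a reference
    recording and reused -- which is exactly what makes AT fragile when
    amplitudes change.
    """
    env = _interior(envelope(rec, cfg.band), rec.fs, cfg.edge_exclude)
    return float(np.mean(cfg.sd_k * env.std(axis=-1)))


def _detect_channel(
    env_ch: np.ndarray,
    fs: float,
    channel_id: str,
    cfg: ATConfig,
    threshold: float,
) -> list[SpindleEvent]:
    starts = window_starts(len(env_ch), fs, cfg.window, cfg.stride)
    mins = slice_windows(env_ch, fs, cfg.window, cfg.stride).min(axis=-1)
    maxs = slice_windows(env_ch, fs, cfg.window, cfg.stride).max(axis=-1)
    mask = mins >= threshold
    events = merge_windows(starts[mask], maxs[mask], channel_id, "AT", window=cfg.window, gap=0.1)
    return [e for e in events if e.duration <= cfg.max_dur + 1e-9]


def at_detect(
    rec: Recording,
    cfg: ATConfig = ATConfig(),
    threshold: float | None = None,
) -> list[SpindleEvent]:
    """Detect events whose envelope stays above ``threshold`` for a full window.

    A window is positive iff min(envelope) >= threshold across its 500 ms;
    positive windows merge exactly like CNN windows (overlap or <= 100 ms
    gap); events longer than ``max_dur`` are discarded. Event score is the
    peak envelope.
    """
    if threshold is None:
        if cfg.threshold_mode == "sd_multiple":
            threshold = sd_threshold(rec, cfg)
        else:
            threshold = calibrate_threshold(rec, cfg)
    if not threshold > 0:
        raise ParameterError("threshold must be positive")
    env = envelope(rec, cfg.band)
    events: list[SpindleEvent] = []
    for c, ch in enumerate(rec.channel_ids):
        events.extend(_detect_channel(env[c], rec.fs, ch, cfg, threshold))
    return events


def calibrate_threshold(
    rec: Recording,
    cfg: ATConfig = ATConfig(),
    per_channel: bool = False,
) -> float | dict[str, float]:
    """Electrode-level threshold giving ~``target_rate`` events/min, averaged.

    Bisection (40 iterations) on each electrode's threshold over
    [0, max envelope]; electrodes where no threshold achieves the target rate
    within 10% (e.g. silent channels) are excluded with a warning. Returns
    the mean of the per-electrode thresholds (or the per-channel dict when
    ``per_channel`` is set).
    """
    if rec.duration < 300:
        warnings.warn(
            f"calibrating on {rec.duration / 60:.1f} min; rates are unstable below 5 min",
            stacklevel=2,
        )
    env = envelope(rec, cfg.band)
    minutes = rec.duration / 60.0
    target = cfg.target_rate
    found: dict[str, float] = {}
    for c, ch in enumerate(rec.channel_ids):
        e = env[c]
        if not e.max() > 0:
            warnings.warn(f"channel {ch} is silent; excluded from calibration", stacklevel=2)
            continue
        lo, hi = 0.0, float(e.max())
        best = None
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if mid == 0.0:
                break
            rate = len(_detect_channel(e, rec.fs, ch, cfg, mid)) / minutes
            if abs(rate - target) <= 0.1 * target:
                best = mid
                break
            if rate > target:
                lo = mid          # too many events -> raise threshold
            else:
                hi = mid
        if best is None:
            warnings.warn(
                f"channel {ch}: no threshold reaches {target}/min within 10%; excluded",
                stacklevel=2,
            )
            continue
        found[ch] = best
    if not found:
        raise CalibrationError("no channel admitted a threshold achieving the target rate")
    if per_channel:
        return found
    return float(np.mean(list(found.values())))
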