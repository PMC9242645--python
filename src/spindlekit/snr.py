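"""CFAR-style band-power SNR detector.

The SNR of a 500 ms window is the ratio (in dB) of power in the spindle band
of interest (9-18 Hz by default) to power in the rest of the 1-100 Hz
spectrum, estimated from a Hann-tapered periodogram of the same window. Being
a ratio, the measure is invariant to the amplitude scale of the recording and
adapts to each electrode's own noise floor -- the property borrowed from
constant-false-alarm-rate detection in radar. Thresholding at the 99th
percentile of the per-channel SNR distribution (floored at 0 dB, i.e. parity
between in-band and out-of-band power) yields a conservative, high-precision
event set that is then used to bootstrap training labels for the CNN.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SamplingError
from .recording import Recording, SpindleEvent
from .windows import slice_windows

__all__ = [
    "SNRTrace",
    "TrainingSet",
    "compute_snr",
    "snr_threshold",
    "snr_detect",
    "build_training_set",
]

DEFAULT_BAND = (9.0, 18.0)
REFERENCE_BAND = (1.0, 100.0)


@dataclass
class SNRTrace:
    """Per-window SNR values (dB) for one channel.

    Windows whose out-of-band power is exactly zero have no defined SNR; they
    are flagged in ``undefined`` and carry NaN in ``values``.
    """

    values: np.ndarray
    window_len: float
    stride: float
    channel_id: str
    undefined: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined is None:
            self.undefined = np.zeros(self.values.shape, dtype=bool)

    def starts(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.stride


def compute_snr(
    rec: Recording,
    band: tuple[float, float] = DEFAULT_BAND,
    window: float = 0.5,
    stride: float = 0.1,
) -> list[SNRTrace]:
    """Sliding-window band-power SNR for every channel.

    ``SNR = 10*log10(P_band / P_rest)`` with ``P_band`` the 9-18 Hz power and
    ``P_rest`` the 1-100 Hz power excluding the band, both from a
    Hann-tapered periodogram of the same 500 ms window.
    """
    if rec.fs < 2 * REFERENCE_BAND[1]:
        raise ParameterError(
            f"fs={rec.fs} too low: the {REFERENCE_BAND} Hz reference band must fit below Nyquist"
        )
    win = int(round(window * rec.fs))
    if win > rec.n_samples:
        raise ParameterError("window longer than recording")
    taper = np.hanning(win)
    freqs = np.fft.rfftfreq(win, 1 / rec.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_rest = (freqs >= REFERENCE_BAND[0]) & (freqs <= REFERENCE_BAND[1]) & ~in_band
    if not in_band.any() or not in_rest.any():
        raise ParameterError("window too short to resolve the analysis bands")

    traces = []
    for c, ch in enumerate(rec.channel_ids):
        segs = slice_windows(rec.data[c], rec.fs, window, stride)
        spec = np.abs(np.fft.rfft(segs * taper, axis=-1)) ** 2
        p_band = spec[:, in_band].sum(axis=-1)
        p_rest = spec[:, in_rest].sum(axis=-1)
        undefined = p_rest == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = 10.0 * np.log10(p_band / p_rest)
        snr[undefined] = np.nan
        traces.append(SNRTrace(snr, window, stride, ch, undefined))
    return traces


def snr_threshold(trace: SNRTrace, percentile: float = 99.0, floor_0db: bool = True) -> float:
    """Detection threshold: the given percentile of the SNR distribution.

    With ``floor_0db`` (the default used in the simulation experiments) the
    threshold is never below 0 dB, the point of parity between in-band and
    out-of-band power.
    """
    vals = trace.values[~trace.undefined]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ParameterError("empty SNR trace")
    thr = float(np.percentile(vals, percentile))
    return max(thr, 0.0) if floor_0db else thr


def snr_detect(
    trace: SNRTrace,
    threshold: float,
    min_dur: float = 0.5,
    max_dur: float = 3.0,
) -> list[SpindleEvent]:
    """Merge supra-threshold windows into events.

    Supra-threshold windows whose 500 ms spans overlap (which includes every
    consecutive run on the 100 ms grid) are combined into one interval from
    the first window's start to the last window's end; intervals shorter
    than ``min_dur`` or longer than ``max_dur`` are discarded (spindle
    duration bounds). The event score is the maximum SNR in the interval.
    """
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    from .windows import merge_windows

    vals = trace.values
    above = np.where(np.isnan(vals), False, vals >= threshold)
    starts = trace.starts()
    merged = merge_windows(
        starts[above], vals[above], trace.channel_id, "SNR",
        window=trace.window_len, gap=0.0,
    )
    return [ev for ev in merged if min_dur - 1e-9 <= ev.duration <= max_dur + 1e-9]


# ------------------------------------------------------------- training set


@dataclass
class TrainingSet:
    """Labelled 500 ms windows for CNN training.

    ``windows`` has shape (n_windows, window_samples); ``labels`` is 1 for
    spindle, 0 for non-spindle. Raw (un-normalised) samples are stored; the
    CNN z-scores each window at its input.
    """

    windows: np.ndarray
    labels: np.ndarray
    channel_ids: list[str]
    t_starts: np.ndarray
    fs: float

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "spindle": int((self.labels == 1).sum()),
            "non_spindle": int((self.labels == 0).sum()),
        }

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.windows).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        return h.hexdigest()[:16]


def _event_windows(ev: SpindleEvent, trace: SNRTrace, window: float) -> list[float]:
    """Window start times tiling one SNR event: peak-SNR window first, then
    non-overlapping neighbours inside the event until exhausted."""
    starts = trace.starts()
    inside = np.where((starts >= ev.t_start - 1e-9) & (starts + window <= ev.t_end + 1e-9))[0]
    if inside.size == 0:
        return [ev.t_start]
    peak = inside[int(np.nanargmax(trace.values[inside]))]
    t_peak = starts[peak]
    chosen = [t_peak]
    t = t_peak - window
    while t >= ev.t_start - 1e-9:
        chosen.append(t)
        t -= window
    t = t_peak + window
    while t + window <= ev.t_end + 1e-9:
        chosen.append(t)
        t += window
    return chosen


def build_training_set(
    rec: Recording,
    events: list[SpindleEvent],
    traces: list[SNRTrace],
    target_total: int = 1500,
    nonspindle_ratio: float = 2.0,
    window: float = 0.5,
    seed: int = 0,
    max_retries: int = 100_000,
) -> TrainingSet:
    """Bootstrap a CNN training set from SNR detections.

    Spindle windows are 500 ms segments inside SNR events (peak-SNR window
    plus non-overlapping neighbours); non-spindle windows are drawn uniformly
    from start times whose window has zero overlap with any SNR event, at
    most ``nonspindle_ratio`` times the number of spindle windows. Around
    ``target_total`` windows total are returned, deterministically under
    ``seed``.
    """
    if not events:
        raise SamplingError(
            "no SNR events to build a training set from; lower the threshold "
            "percentile or provide a longer recording"
        )
    if len(events) < 50:
        warnings.warn(
            f"only {len(events)} SNR events available; CNN training may be underpowered",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    trace_by_ch = {t.channel_id: t for t in traces}
    win = int(round(window * rec.fs))

    pos: list[tuple[str, float]] = []
    for ev in events:
        for t0 in _event_windows(ev, trace_by_ch[ev.channel_id], window):
            pos.append((ev.channel_id, float(t0)))
    n_pos_target = max(1, int(round(target_total / (1.0 + nonspindle_ratio))))
    if len(pos) > n_pos_target:
        keep = rng.choice(len(pos), size=n_pos_target, replace=False)
        pos = [pos[i] for i in sorted(keep)]

    n_neg = min(int(nonspindle_ratio * len(pos)), max(0, target_total - len(pos)))
    by_ch: dict[str, list[SpindleEvent]] = {}
    for ev in events:
        by_ch.setdefault(ev.channel_id, []).append(ev)
    neg: list[tuple[str, float]] = []
    t_max = rec.duration - window
    if t_max <= 0:
        raise SamplingError("recording shorter than one window")
    retries = 0
    while len(neg) < n_neg:
        if retries > max_retries:
            raise SamplingError(
                "recording too dense in SNR events to supply non-overlapping negatives"
            )
        ch = rec.channel_ids[rng.integers(0, rec.n_channels)]
        t0 = rng.uniform(0.0, t_max)
        if any(ev.t_start < t0 + window and t0 < ev.t_end for ev in by_ch.get(ch, [])):
            retries += 1
            continue
        neg.append((ch, float(t0)))

    items = [(ch, t0, 1) for ch, t0 in pos] + [(ch, t0, 0) for ch, t0 in neg]
    windows = np.empty((len(items), win))
    labels = np.empty(len(items), dtype=int)
    chans, starts = [], []
    for k, (ch, t0, lab) in enumerate(items):
        i0 = min(int(round(t0 * rec.fs)), rec.n_samples - win)
        windows[k] = rec.data[rec.channel_index(ch), i0 : i0 + win]
        labels[k] = lab
        chans.append(ch)
        starts.append(i0 / rec.fs)
    return TrainingSet(windows, labels, chans, np.asarray(starts), rec.fs)
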