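"""Validation and spatiotemporal analyses.

Covers: Welch PSD contrast between detected-spindle and matched non-spindle
windows; time-shifted averaging (events aligned at their largest positive
deflection before averaging, which reveals oscillatory structure without
narrowband filtering); precision/recall scoring against a ground-truth
manifest; spatial-extent classes (local 1-2 sites, regional 3-10,
multi-area >10 within a 500 ms detection window); array-level
("multi-electrode") event rates; cortical-region participation; and the
rotating-wave direction indices

    alpha_aligned(t) = | (1/N) sum_n exp(+i x_{n,t}) exp(i theta_n) |
    alpha_anti(t)    = | (1/N) sum_n exp(-i x_{n,t}) exp(i theta_n) |

with x_{n,t} the instantaneous phase of the 9-18 Hz band of channel n and
theta_n the electrode polar angle. A wave rotating with polar wavenumber
gamma=+1 has x_{n,t} = w*t - theta_n, so the aligned sum collapses to
|exp(i*w*t)| = 1; the anti index reduces to the montage constant
|mean_n exp(2i theta_n)|, which for spread-out montages sits near the
1/sqrt(N) no-synchrony floor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.signal import hilbert

from .errors import ParameterError
from .preprocess import bandpass_array
from .recording import Recording, SpindleEvent
from .simulate import GroundTruthManifest, ManifestEntry

__all__ = [
    "ExtentClass",
    "RotationResult",
    "welch_contrast",
    "time_shifted_average",
    "score_detection",
    "classify_extent",
    "array_level_events",
    "multi_electrode_rate",
    "region_participation",
    "rotation_indices",
    "peak_band_amplitude",
]


# ------------------------------------------------------------ PSD contrast


def _nonoverlapping_event_windows(events: Sequence[SpindleEvent], window: float) -> list[tuple[str, float]]:
    out = []
    for ev in events:
        t = ev.t_start
        added = 0
        while t + window <= ev.t_end + 1e-9:
            out.append((ev.channel_id, t))
            t += window
            added += 1
        if added == 0:
            out.append((ev.channel_id, ev.t_start))   # events shorter than one window
    return out


def _matched_nonevent_windows(
    rec: Recording,
    events: Sequence[SpindleEvent],
    count: int,
    window: float,
    rng: np.random.Generator,
    max_retries: int = 100_000,
) -> list[tuple[str, float]]:
    by_ch: dict[str, list[SpindleEvent]] = {}
    for ev in events:
        by_ch.setdefault(ev.channel_id, []).append(ev)
    out: list[tuple[str, float]] = []
    t_max = rec.duration - window
    retries = 0
    while len(out) < count:
        if retries > max_retries:
            raise ParameterError("could not draw enough non-event windows")
        ch = rec.channel_ids[rng.integers(0, rec.n_channels)]
        t0 = rng.uniform(0.0, t_max)
        if any(ev.t_start < t0 + window and t0 < ev.t_end for ev in by_ch.get(ch, [])):
            retries += 1
            continue
        out.append((ch, float(t0)))
    return out


def _mean_psd(rec: Recording, windows: list[tuple[str, float]], win: int) -> np.ndarray:
    taper = np.hanning(win)
    scale = 1.0 / (rec.fs * (taper**2).sum())
    acc = np.zeros(win // 2 + 1)
    for ch, t0 in windows:
        i0 = min(int(round(t0 * rec.fs)), rec.n_samples - win)
        seg = rec.data[rec.channel_index(ch), i0 : i0 + win]
        acc += scale * np.abs(np.fft.rfft(seg * taper)) ** 2
    return acc / len(windows)


def welch_contrast(
    rec: Recording,
    events: Sequence[SpindleEvent],
    n_matched_nonspindle: Optional[int] = None,
    seed: int = 0,
    window: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average PSD over event windows versus matched non-event windows.

    Events are tiled with non-overlapping 500 ms windows; the same number of
    random windows with zero event overlap forms the control. Returns
    ``(freqs, psd_spindle, psd_nonspindle)``.
    """
    if len(events) < 10:
        raise ParameterError(f"need at least 10 events for a stable PSD, got {len(events)}")
    rng = np.random.default_rng(seed)
    win = int(round(window * rec.fs))
    ev_windows = _nonoverlapping_event_windows(events, window)
    n_ctrl = n_matched_nonspindle or len(ev_windows)
    ctrl_windows = _matched_nonevent_windows(rec, events, n_ctrl, window, rng)
    freqs = np.fft.rfftfreq(win, 1 / rec.fs)
    return freqs, _mean_psd(rec, ev_windows, win), _mean_psd(rec, ctrl_windows, win)


# --------------------------------------------------- time-shifted averaging


def time_shifted_average(
    rec: Recording,
    events: Sequence[SpindleEvent],
    n_matched_nonspindle: Optional[int] = None,
    seed: int = 0,
    half_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average of event segments aligned at their largest positive sample.

    ``rec`` should carry only a 1 Hz highpass (the point of the control is to
    avoid narrowband filtering). Each event is shifted so its maximum
    positive value sits at lag 0, then segments of +-``half_width`` s are
    averaged; the same procedure is applied to matched random non-event
    windows. Returns ``(lags_s, avg_spindle, avg_nonspindle)``.
    """
    if len(events) < 20:
        raise ParameterError(f"need at least 20 events for a stable average, got {len(events)}")
    rng = np.random.default_rng(seed)
    hw = int(round(half_width * rec.fs))

    def aligned_average(windows: list[tuple[str, float, float]]) -> np.ndarray:
        acc = np.zeros(2 * hw + 1)
        count = 0
        for ch, t0, t1 in windows:
            c = rec.channel_index(ch)
            i0 = int(round(t0 * rec.fs))
            i1 = min(int(round(t1 * rec.fs)), rec.n_samples)
            if i1 <= i0:
                continue
            peak = i0 + int(np.argmax(rec.data[c, i0:i1]))
            lo, hi = peak - hw, peak + hw + 1
            if lo < 0 or hi > rec.n_samples:
                continue
            acc += rec.data[c, lo:hi]
            count += 1
        if count == 0:
            raise ParameterError("no event fit inside the recording with the requested half width")
        return acc / count

    ev_windows = [(e.channel_id, e.t_start, e.t_end) for e in events]
    n_ctrl = n_matched_nonspindle or len(events)
    durations = np.array([e.duration for e in events])
    ctrl = _matched_nonevent_windows(rec, events, n_ctrl, float(durations.mean()), rng)
    ctrl_windows = [(ch, t0, t0 + float(durations.mean())) for ch, t0 in ctrl]
    lags = np.arange(-hw, hw + 1) / rec.fs
    return lags, aligned_average(ev_windows), aligned_average(ctrl_windows)


# ------------------------------------------------------------------ scoring


def _match_events(
    events: Sequence[SpindleEvent],
    truths: Sequence[ManifestEntry],
    min_overlap: float,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching by overlap (max cardinality, then overlap).

    Eligible pairs share a channel and overlap by at least ``min_overlap`` of
    the shorter interval; the assignment maximises the number of matches and,
    among those, the total overlap.
    """
    if not events or not truths:
        return []
    from scipy.optimize import linear_sum_assignment

    big = 1e6
    w = np.zeros((len(events), len(truths)))
    for i, ev in enumerate(events):
        for j, tr in enumerate(truths):
            if ev.channel_id != tr.channel_id:
                continue
            ov = max(0.0, min(ev.t_end, tr.t_end) - max(ev.t_start, tr.t_start))
            shorter = min(ev.t_end - ev.t_start, tr.t_end - tr.t_start)
            if shorter > 0 and ov >= min_overlap * shorter - 1e-12:
                w[i, j] = big + ov
    rows, cols = linear_sum_assignment(w, maximize=True)
    return [(i, j) for i, j in zip(rows, cols) if w[i, j] > 0]


def score_detection(
    events: Sequence[SpindleEvent],
    manifest: GroundTruthManifest,
    min_overlap: float = 0.5,
) -> tuple[float, float, float]:
    """Event-level (precision, recall, F1) against the true spindle table.

    A detected event matches a true spindle iff their intervals overlap by at
    least ``min_overlap`` of the shorter interval; matching is one-to-one,
    greedy by overlap.
    """
    truths = list(manifest.spindles())
    matches = _match_events(events, truths, min_overlap)
    tp = len(matches)
    precision = tp / len(events) if events else 0.0
    recall = tp / len(truths) if truths else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


# ------------------------------------------------------ extent and rates


@dataclass(frozen=True)
class ExtentClass:
    """Spatial extent of spindle activity in one detection window."""

    window_id: int
    t_start: float
    n_sites: int
    label: str                 # local | regional | multi_area

    @staticmethod
    def classify(n_sites: int) -> str:
        if n_sites < 1:
            raise ParameterError("extent requires at least one site")
        if n_sites <= 2:
            return "local"
        if n_sites <= 10:
            return "regional"
        return "multi_area"


def classify_extent(
    events: Sequence[SpindleEvent],
    window: float = 0.5,
    stride: float = 0.1,
) -> list[ExtentClass]:
    """Per-detection-window co-occurrence classes.

    For every window of the detection grid that overlaps at least one event,
    count the channels with an overlapping event and classify: local (1-2
    sites), regional (3-10), multi-area (>10). An event spanning many windows
    contributes to each one, so an event that starts local and becomes
    distributed is counted in both regimes.
    """
    if not events:
        return []
    t_end = max(e.t_end for e in events)
    n_win = int(np.floor((t_end - window) / stride + 1e-9)) + 1
    out = []
    for w in range(max(n_win, 1)):
        t0 = w * stride
        t1 = t0 + window
        sites = {e.channel_id for e in events if e.t_start < t1 - 1e-9 and t0 < e.t_end - 1e-9}
        if sites:
            out.append(ExtentClass(w, t0, len(sites), ExtentClass.classify(len(sites))))
    return out


def array_level_events(events: Sequence[SpindleEvent]) -> list[list[SpindleEvent]]:
    """Group temporally overlapping events (any channels) into array-level events.

    Connected components under interval overlap: a sweep in start order links
    an event to the open component when it starts before the component's
    current end (transitive, so chains A-B, B-C group even if A and C do not
    directly overlap).
    """
    evs = sorted(events, key=lambda e: (e.t_start, e.t_end))
    groups: list[list[SpindleEvent]] = []
    cur: list[SpindleEvent] = []
    cur_end = -np.inf
    for e in evs:
        if cur and e.t_start < cur_end - 1e-9:
            cur.append(e)
            cur_end = max(cur_end, e.t_end)
        else:
            if cur:
                groups.append(cur)
            cur = [e]
            cur_end = e.t_end
    if cur:
        groups.append(cur)
    return groups


def multi_electrode_rate(
    events: Sequence[SpindleEvent],
    duration_min: float,
    class_filter: Optional[str] = None,
) -> float:
    """Array-level events per minute.

    Simultaneous events across electrodes count once. ``class_filter``
    restricts to array-level events whose participating-channel count falls
    in the named extent class (local/regional/multi_area).
    """
    if duration_min <= 0:
        raise ParameterError("duration must be positive")
    groups = array_level_events(events)
    if class_filter is not None:
        groups = [
            g for g in groups
            if ExtentClass.classify(len({e.channel_id for e in g})) == class_filter
        ]
    return len(groups) / duration_min


def region_participation(
    events: Sequence[SpindleEvent],
    region_labels: dict[str, str],
    grouping: Optional[Callable[[str], str] | dict[str, str]] = None,
) -> list[float]:
    """Percentage of recorded groups participating in each array-level event.

    ``region_labels`` maps channel id -> anatomical label; ``grouping``
    optionally maps labels to a coarser level (lobe, system). Returns one
    percentage per array-level event:
    100 * |groups among participating channels| / |groups recorded|.
    """
    if not region_labels:
        raise ParameterError("region labels are required")
    if grouping is None:
        gfun = lambda lab: lab
    elif isinstance(grouping, dict):
        gfun = lambda lab: grouping[lab]
    else:
        gfun = grouping
    recorded = {gfun(lab) for lab in region_labels.values()}
    out = []
    for group in array_level_events(events):
        try:
            present = {gfun(region_labels[e.channel_id]) for e in group}
        except KeyError as e:
            raise ParameterError(f"missing region label for channel {e}") from None
        out.append(100.0 * len(present) / len(recorded))
    return out


# ---------------------------------------------------------- rotating waves


@dataclass
class RotationResult:
    """Aligned / anti-aligned rotation indices for one array-level window."""

    alpha_aligned_t: np.ndarray
    alpha_anti_t: np.ndarray
    mean_aligned: float
    mean_anti: float
    times: np.ndarray


def rotation_indices(
    rec: Recording,
    t_start: float,
    t_end: float,
    theta_n: Optional[np.ndarray] = None,
    band: tuple[float, float] = (9.0, 18.0),
    edge_trim: float = 0.1,
    mode: str = "magnitude",
) -> RotationResult:
    """Rotation indices over one event interval (see module docstring).

    Instantaneous phases come from the analytic signal of the band-passed
    channels; the scalar summaries are time means over the event interior
    (``edge_trim`` seconds removed at each end when the event is long enough,
    against Hilbert edge effects). ``mode`` selects how alpha(t) is reduced:
    ``magnitude`` (default, per-sample |complex mean| then time mean),
    ``real`` (per-sample real part), or ``modulus_of_mean`` (|time mean of
    the complex index|).
    """
    theta = theta_n if theta_n is not None else rec.polar_angle
    if theta is None:
        raise ParameterError("electrode polar angles are required")
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (rec.n_channels,):
        raise ParameterError("need one polar angle per channel")
    if rec.n_channels < 3:
        raise ParameterError("rotation indices need at least 3 angled channels")
    if mode not in ("magnitude", "real", "modulus_of_mean"):
        raise ParameterError(f"unknown mode {mode!r}")

    i0 = max(0, int(round(t_start * rec.fs)))
    i1 = min(rec.n_samples, int(round(t_end * rec.fs)))
    if i1 - i0 < 3:
        raise ParameterError("event interval too short")
    bp = bandpass_array(rec.data[:, i0:i1], rec.fs, band[0], band[1])
    phases = np.angle(hilbert(bp, axis=-1))

    k = int(round(edge_trim * rec.fs))
    if 2 * k >= phases.shape[-1]:
        k = 0
    sl = slice(k, phases.shape[-1] - k if k else None)
    ph = phases[:, sl]
    rot = np.exp(1j * theta[:, None])
    z_aligned = np.mean(np.exp(1j * ph) * rot, axis=0)
    z_anti = np.mean(np.exp(-1j * ph) * rot, axis=0)
    if mode == "modulus_of_mean":
        mean_al, mean_an = float(np.abs(z_aligned.mean())), float(np.abs(z_anti.mean()))
        a_t, b_t = np.abs(z_aligned), np.abs(z_anti)
    elif mode == "real":
        a_t, b_t = np.real(z_aligned), np.real(z_anti)
        mean_al, mean_an = float(a_t.mean()), float(b_t.mean())
    else:
        a_t, b_t = np.abs(z_aligned), np.abs(z_anti)
        mean_al, mean_an = float(a_t.mean()), float(b_t.mean())
    times = (np.arange(i0, i1)[sl]) / rec.fs
    return RotationResult(a_t, b_t, mean_al, mean_an, times)


def peak_band_amplitude(
    rec: Recording,
    event: SpindleEvent,
    band: tuple[float, float] = (9.0, 18.0),
) -> float:
    """Peak Fourier amplitude in ``band`` over the event window (rectangular taper)."""
    seg = rec.data[rec.channel_index(event.channel_id),
                   max(0, int(round(event.t_start * rec.fs))):
                   min(rec.n_samples, int(round(event.t_end * rec.fs)))]
    freqs = np.fft.rfftfreq(len(seg), 1 / rec.fs)
    spec = np.abs(np.fft.rfft(seg)) / len(seg) * 2.0
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ParameterError("event too short to resolve the band")
    return float(spec[mask].max())
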