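"""Core containers: multichannel recordings and detected spindle events.

Time convention used throughout the package: times are seconds from the start
of the recording, intervals are half-open ``[t_start, t_end)``, and sample ``k``
covers ``[k/fs, (k+1)/fs)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["Recording", "SpindleEvent", "validate_events"]

#: detector tags a SpindleEvent may carry
DETECTORS = ("SNR", "CNN", "AT")


@dataclass
class Recording:
    """A channels x samples real-valued recording.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``; units are whatever the
        source provides (typically microvolts) and are never rescaled on read.
    fs
        Sampling rate in Hz, must be positive.
    channel_ids
        One string per channel.
    region_labels
        Optional per-channel anatomical label (region, lobe, ...).
    polar_angle
        Optional per-channel polar angle in radians with respect to the
        anterior sagittal midline, in ``[-pi, pi]``.
    meta
        Free-form provenance mapping.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    region_labels: Optional[list[str]] = None
    polar_angle: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {self.data.shape[0]} channels"
            )
        if self.region_labels is not None and len(self.region_labels) != self.n_channels:
            raise ValueError("region_labels length mismatch")
        if self.polar_angle is not None:
            self.polar_angle = np.asarray(self.polar_angle, dtype=float)
            if self.polar_angle.shape != (self.n_channels,):
                raise ValueError("polar_angle must have one angle per channel")
            if np.any(np.abs(self.polar_angle) > np.pi + 1e-9):
                raise ValueError("polar_angle values must lie in [-pi, pi]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel {channel_id!r}") from None

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording carrying new sample data."""
        return replace(self, data=np.asarray(data, dtype=float), meta=dict(self.meta))

    def slice_time(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples of all channels covering ``[t_start, t_end)``."""
        i0 = max(0, int(round(t_start * self.fs)))
        i1 = min(self.n_samples, int(round(t_end * self.fs)))
        return self.data[:, i0:i1]


@dataclass(frozen=True)
class SpindleEvent:
    """One detected event on one channel.

    ``score`` is detector-dependent: posterior probability for the CNN,
    peak SNR in dB for the SNR detector, peak envelope amplitude for AT.
    """

    channel_id: str
    t_start: float
    t_end: float
    score: float
    detector: str

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end must exceed t_start ({self.t_start}, {self.t_end})")
        if self.detector not in DETECTORS:
            raise ValueError(f"detector must be one of {DETECTORS}, got {self.detector!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def overlap(self, other: "SpindleEvent") -> float:
        """Length in seconds of the intersection with ``other``."""
        return max(0.0, min(self.t_end, other.t_end) - max(self.t_start, other.t_start))


def validate_events(events: Sequence[SpindleEvent]) -> None:
    """Check the per-channel, per-detector non-overlap invariant.

    Raises ``ValueError`` naming the first offending pair.
    """
    groups: dict[tuple[str, str], list[SpindleEvent]] = {}
    for ev in events:
        groups.setdefault((ev.channel_id, ev.detector), []).append(ev)
    for (ch, det), evs in groups.items():
        evs = sorted(evs, key=lambda e: e.t_start)
        for a, b in zip(evs, evs[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError(
                    f"overlapping {det} events on channel {ch}: "
                    f"[{a.t_start:.3f}, {a.t_end:.3f}) and [{b.t_start:.3f}, {b.t_end:.3f})"
                )
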