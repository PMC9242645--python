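"""Sliding-window grid arithmetic and the shared window-merging rule.

Every detector in the package scores 500 ms windows on a 100 ms grid; the
merge rule below is shared code, so identical positive-window sets give
identical events regardless of which detector produced them.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ParameterError
from .recording import SpindleEvent

__all__ = ["window_starts", "slice_windows", "merge_windows"]

_EPS = 1e-9


def window_starts(n_samples: int, fs: float, window: float = 0.5, stride: float = 0.1) -> np.ndarray:
    """Start times (s) of all full windows covering a recording of ``n_samples``."""
    win = int(round(window * fs))
    step = int(round(stride * fs))
    if win > n_samples:
        raise ParameterError(
            f"window of {window} s ({win} samples) longer than recording ({n_samples} samples)"
        )
    if step < 1:
        raise ParameterError(f"stride {stride} s is below one sample at fs={fs}")
    n_win = (n_samples - win) // step + 1
    return np.arange(n_win) * step / fs


def slice_windows(
    x: np.ndarray, fs: float, window: float = 0.5, stride: float = 0.1
) -> np.ndarray:
    """View of shape (n_windows, win_samples) over a 1-D signal."""
    win = int(round(window * fs))
    step = int(round(stride * fs))
    if win > x.shape[-1]:
        raise ParameterError("window longer than signal")
    view = np.lib.stride_tricks.sliding_window_view(x, win, axis=-1)
    return view[..., ::step, :]


def merge_windows(
    starts: Sequence[float],
    scores: Sequence[float],
    channel_id: str,
    detector: str,
    window: float = 0.5,
    gap: float = 0.1,
) -> list[SpindleEvent]:
    """Merge positive windows into events.

    Windows are intervals ``[s, s + window)``. Overlapping windows are
    combined, and neighbouring windows are absorbed when the gap between the
    end of the running event and the next window start is at most ``gap``
    (boundary inclusive). The event runs from the start of its first window
    to the end of its last; the score is the maximum window score.
    """
    order = np.argsort(np.asarray(starts, dtype=float), kind="stable")
    events: list[SpindleEvent] = []
    cur_start = cur_end = None
    cur_score = -np.inf
    for i in order:
        s = float(starts[i])
        e = s + window
        if cur_start is None:
            cur_start, cur_end, cur_score = s, e, float(scores[i])
        elif s <= cur_end + gap + _EPS:
            cur_end = max(cur_end, e)
            cur_score = max(cur_score, float(scores[i]))
        else:
            events.append(SpindleEvent(channel_id, cur_start, cur_end, cur_score, detector))
            cur_start, cur_end, cur_score = s, e, float(scores[i])
    if cur_start is not None:
        events.append(SpindleEvent(channel_id, cur_start, cur_end, cur_score, detector))
    return events
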