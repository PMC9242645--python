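"""End-to-end convenience wrappers: the two-step SNR -> CNN pipeline.

The two-step protocol: (1) run the conservative SNR detector to obtain a
high-precision set of marked spindles, (2) bootstrap a balanced training set
from those marks (non-spindles at most twice the spindles), (3) train a
subject-specific CNN on the marked windows, (4) slide the CNN over the whole
recording to detect the comprehensive event set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .at import ATConfig, at_detect
from .cnn import (
    ArchitectureSpec,
    DetectorModel,
    TrainConfig,
    build_model,
    cnn_detect,
    predict_windows,
    train,
)
from .errors import ParameterError
from .preprocess import bandpass, common_average_reference, remove_line_noise
from .recording import Recording, SpindleEvent
from .snr import build_training_set, compute_snr, snr_detect, snr_threshold

__all__ = ["PipelineResult", "preprocess_standard", "snr_events", "bootstrap_cnn", "detect"]


@dataclass
class PipelineResult:
    """Everything the two-step pipeline produced."""

    snr_events: list[SpindleEvent]
    model: DetectorModel
    cnn_events: list[SpindleEvent]
    thresholds: dict[str, float] = field(default_factory=dict)


def preprocess_standard(
    rec: Recording,
    line_freq: Optional[float] = None,
    band: tuple[float, float] = (1.0, 100.0),
    car: bool = False,
) -> Recording:
    """Line-noise removal, 1-100 Hz bandpass, optional common average reference.

    The upper band edge is clipped below Nyquist so the same call works for
    low sampling rates (e.g. 200 Hz surrogates).
    """
    out = rec
    if line_freq is not None:
        out = remove_line_noise(out, line_freq)
    hi = min(band[1], 0.475 * rec.fs)
    out = bandpass(out, band[0], hi)
    if car:
        out = common_average_reference(out)
    return out


def snr_events(
    rec: Recording,
    band: tuple[float, float] = (9.0, 18.0),
    percentile: float = 99.0,
    floor_0db: bool = True,
) -> tuple[list[SpindleEvent], list]:
    """SNR detections with per-channel thresholds; returns (events, traces)."""
    traces = compute_snr(rec, band=band)
    events: list[SpindleEvent] = []
    for trace in traces:
        thr = snr_threshold(trace, percentile, floor_0db)
        events.extend(snr_detect(trace, thr))
    return events, traces


def bootstrap_cnn(
    rec: Recording,
    seed: int = 0,
    percentile: float = 99.0,
    target_total: int = 1500,
    train_config: Optional[TrainConfig] = None,
    arch: Optional[ArchitectureSpec] = None,
) -> PipelineResult:
    """The full two-step pipeline on one (preprocessed) recording."""
    events, traces = snr_events(rec, percentile=percentile)
    ts = build_training_set(rec, events, traces, target_total=target_total, seed=seed)
    model = build_model(arch or ArchitectureSpec(fs=rec.fs), seed=seed)
    train(model, ts, train_config or TrainConfig(seed=seed))
    preds = predict_windows(model, rec)
    return PipelineResult(events, model, cnn_detect(preds))


def detect(
    rec: Recording,
    method: str,
    model: Optional[DetectorModel] = None,
    percentile: float = 99.0,
    floor_0db: bool = True,
    at_config: Optional[ATConfig] = None,
    at_threshold: Optional[float] = None,
) -> list[SpindleEvent]:
    """Uniform entry point for the three detectors."""
    method = method.lower()
    if method == "snr":
        return snr_events(rec, percentile=percentile, floor_0db=floor_0db)[0]
    if method == "cnn":
        if model is None:
            raise ParameterError("CNN detection requires a trained model")
        return cnn_detect(predict_windows(model, rec))
    if method == "at":
        cfg = at_config or ATConfig()
        return at_detect(rec, cfg, threshold=at_threshold)
    raise ParameterError(f"unknown method {method!r}; expected snr, cnn or at")
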