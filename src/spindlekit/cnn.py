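"""Subject-specific 1-D convolutional spindle detector.

Architecture: five convolutional layers (32, 64, 128, 192, 256 filters), each
followed by max-pooling and ReLU, then four fully connected layers (128, 64,
32, 2) with ReLU between them and a softmax head that returns the spindle
probability of a 500 ms window. First-layer kernels span roughly one
oscillation cycle (70-120 ms; 90 ms default), which is what makes the filters
match the spindle waveform; all sample-domain sizes are derived from the
sampling rate, which is the whole of the per-modality tailoring rule.

Windows are z-scored at the input, so detection depends on waveform shape,
not on absolute amplitude -- the property that lets the model find both
large- and small-amplitude spindles.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import nn
from .errors import ArchitectureError, ParameterError, TrainingError
from .recording import Recording, SpindleEvent
from .snr import TrainingSet
from .windows import merge_windows, slice_windows, window_starts

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "DetectorModel",
    "WindowPredictions",
    "build_model",
    "train",
    "predict_windows",
    "cnn_detect",
    "saliency_map",
    "feature_maps",
    "cronbach_alpha",
    "hyperparameter_sensitivity",
    "save_model",
    "load_model",
]


@dataclass
class ArchitectureSpec:
    """Layer layout of the detector; all sizes in ms are converted via ``fs``."""

    fs: float
    conv_filters: tuple[int, ...] = (32, 64, 128, 192, 256)
    fc_sizes: tuple[int, ...] = (128, 64, 32, 2)
    kernel_ms: tuple[float, ...] = (90.0, 45.0, 22.0, 11.0, 6.0)
    pool: tuple[int, ...] = (2, 2, 2, 2, 2)
    input_ms: float = 500.0

    def __post_init__(self) -> None:
        if len(self.kernel_ms) != len(self.conv_filters) or len(self.pool) != len(self.conv_filters):
            raise ArchitectureError("conv_filters, kernel_ms and pool must have equal length")
        if self.fc_sizes[-1] != 2:
            raise ArchitectureError("final fully connected layer must have size 2")
        self.feature_lengths()  # validates the pooling chain

    @property
    def input_samples(self) -> int:
        return int(round(self.input_ms / 1000.0 * self.fs))

    def kernel_samples(self) -> list[int]:
        return [max(1, int(round(ms / 1000.0 * self.fs))) for ms in self.kernel_ms]

    def feature_lengths(self) -> list[int]:
        """Feature-map length after each conv+pool block; raises on collapse."""
        length = self.input_samples
        out = []
        for i, p in enumerate(self.pool):
            length = length // p          # same-padding conv preserves length
            if length < 1:
                raise ArchitectureError(
                    f"pooling chain collapses the feature map to length 0 at conv layer {i + 1}"
                )
            out.append(length)
        return out

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 6
    optimizer: str = "adam"


@dataclass
class DetectorModel:
    """A (possibly trained) detector: architecture, weights and provenance."""

    arch: ArchitectureSpec
    net: nn.Sequential
    train_config: Optional[TrainConfig] = None
    provenance: dict = field(default_factory=dict)
    trained: bool = False
    history: dict = field(default_factory=dict)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Spindle probability for each row of ``windows`` (raw samples)."""
        x = _zscore_windows(np.atleast_2d(np.asarray(windows, dtype=float)))
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            logits = self.net.forward(x[i : i + batch_size, None, :])
            out[i : i + batch_size] = nn.softmax(logits)[:, 1]
        return out

    def weights_digest(self) -> str:
        h = hashlib.sha256()
        for p in self.net.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()[:16]


@dataclass
class WindowPredictions:
    """Per-channel spindle probability on the sliding-window grid."""

    starts: np.ndarray                  # shared start times, s
    probs: np.ndarray                   # (n_channels, n_windows) in [0, 1]
    channel_ids: list[str]
    window: float = 0.5
    stride: float = 0.1


def _zscore_windows(w: np.ndarray) -> np.ndarray:
    mu = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    return (w - mu) / np.maximum(sd, 1e-8)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> DetectorModel:
    """Untrained detector with He-initialised weights (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    cin = 1
    for f, k, p in zip(spec.conv_filters, spec.kernel_samples(), spec.pool):
        layers.append(nn.Conv1d(cin, f, k, rng))
        layers.append(nn.MaxPool1d(p))
        layers.append(nn.ReLU())
        cin = f
    layers.append(nn.Flatten())
    d = spec.conv_filters[-1] * spec.feature_lengths()[-1]
    for i, width in enumerate(spec.fc_sizes):
        layers.append(nn.Linear(d, width, rng))
        if i < len(spec.fc_sizes) - 1:
            layers.append(nn.ReLU())
        d = width
    return DetectorModel(arch=spec, net=nn.Sequential(layers))


def train(
    model: DetectorModel,
    ts: TrainingSet,
    config: Optional[TrainConfig] = None,
) -> DetectorModel:
    """Train in place by minimising cross-entropy against the SNR labels.

    A held-out fraction (default 10%) monitors generalisation: training stops
    early when the held-out loss has not improved for ``patience`` epochs and
    the best weights are restored. Deterministic per seed on a single thread.
    """
    config = config or TrainConfig()
    labels = np.asarray(ts.labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise TrainingError("training set must contain both spindle and non-spindle windows")
    if ts.windows.shape[1] != model.arch.input_samples:
        raise TrainingError(
            f"training windows have {ts.windows.shape[1]} samples, "
            f"model expects {model.arch.input_samples}"
        )
    rng = np.random.default_rng(config.seed)
    x = _zscore_windows(np.asarray(ts.windows, dtype=float))

    # stratified train/validation split
    val_idx, train_idx = [], []
    for cls in (0, 1):
        idx = np.where(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(config.val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    val_idx = np.array(sorted(val_idx))
    train_idx = np.array(train_idx)
    if len(train_idx) == 0:
        raise TrainingError("training set too small for the requested validation fraction")

    xv, yv = x[val_idx, None, :], labels[val_idx]
    opt = nn.Adam(model.net.params(), lr=config.lr)

    def val_loss() -> float:
        loss, _ = nn.softmax_cross_entropy(model.net.forward(xv), yv)
        return loss

    history = {"val_loss": [val_loss()], "train_loss": []}
    best = (history["val_loss"][0], model.net.state())
    stale = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            batch = train_idx[order[i : i + config.batch_size]]
            logits = model.net.forward(x[batch, None, :])
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[batch])
            model.net.backward(dlogits)
            opt.step(model.net.grads())
            epoch_loss += loss * len(batch)
        history["train_loss"].append(epoch_loss / len(train_idx))
        vl = val_loss()
        history["val_loss"].append(vl)
        if vl < best[0] - 1e-6:
            best = (vl, model.net.state())
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.net.load_state(best[1])
    model.trained = True
    model.train_config = config
    model.history = history
    model.provenance = {"training_set_digest": ts.digest(), "n_windows": len(labels)}
    return model


def predict_windows(model: DetectorModel, rec: Recording) -> WindowPredictions:
    """Slide the detector over every channel independently."""
    win = model.arch.input_samples
    if rec.n_samples < win:
        raise ParameterError("recording shorter than one detection window")
    stride = 0.1
    starts = window_starts(rec.n_samples, rec.fs, model.arch.input_ms / 1000.0, stride)
    probs = np.empty((rec.n_channels, len(starts)))
    for c in range(rec.n_channels):
        segs = slice_windows(rec.data[c], rec.fs, model.arch.input_ms / 1000.0, stride)
        probs[c] = model.predict_proba(segs)
    return WindowPredictions(starts, probs, list(rec.channel_ids))


def cnn_detect(
    preds: WindowPredictions,
    threshold: float = 0.5,
    gap: float = 0.1,
) -> list[SpindleEvent]:
    """Merge positive windows (probability >= threshold) into events."""
    events: list[SpindleEvent] = []
    for c, ch in enumerate(preds.channel_ids):
        mask = preds.probs[c] >= threshold
        events.extend(
            merge_windows(
                preds.starts[mask], preds.probs[c][mask], ch, "CNN",
                window=preds.window, gap=gap,
            )
        )
    return events


def saliency_map(
    model: DetectorModel,
    window: np.ndarray,
    times_input: bool = False,
) -> np.ndarray:
    """Per-sample attribution of the spindle logit for one 500 ms window.

    The default is the bare gradient magnitude |d(spindle logit)/d(x_t)|,
    computed on the z-scored input the network actually sees. With
    ``times_input`` the gradient is multiplied by the input magnitude
    (gradient-times-input attribution), which localises the attribution on
    the oscillatory part of the signal and is the form used for the
    which-part-of-the-signal-matters analyses. Warns (but proceeds) when the
    model is untrained.
    """
    if not model.trained:
        warnings.warn("saliency of an untrained model reflects the random initialisation",
                      stacklevel=2)
    x = _zscore_windows(np.asarray(window, dtype=float)[None, :])[:, None, :]
    model.net.forward(x)
    dlogits = np.array([[0.0, 1.0]])
    dx = model.net.backward(dlogits)
    g = np.abs(dx[0, 0])
    if times_input:
        g = g * np.abs(x[0, 0])
    return g


def feature_maps(model: DetectorModel, window: np.ndarray) -> list[np.ndarray]:
    """Post-ReLU activations of each conv block, shapes (n_filters, length)."""
    x = _zscore_windows(np.asarray(window, dtype=float)[None, :])[:, None, :]
    maps = []
    for i, layer in enumerate(model.net.layers):
        x = layer.forward(x)
        if isinstance(layer, nn.ReLU) and i + 1 < len(model.net.layers) and not isinstance(
            model.net.layers[i + 1], nn.Linear
        ):
            maps.append(x[0].copy())
    return maps


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha across the rows (items) of ``item_matrix``.

    ``alpha = k/(k-1) * (1 - sum_i var_i / var_total)`` where ``var_i`` is the
    variance of item i over observations and ``var_total`` the variance of
    the per-observation sum across items.
    """
    m = np.asarray(item_matrix, dtype=float)
    k = m.shape[0]
    if k < 2:
        raise ParameterError("Cronbach's alpha needs at least two items")
    item_var = m.var(axis=1, ddof=1).sum()
    total_var = m.sum(axis=0).var(ddof=1)
    if total_var == 0:
        return 0.0
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def hyperparameter_sensitivity(
    ts: TrainingSet,
    rec: Recording,
    grid: Sequence[dict],
    seed: int = 0,
    base_config: Optional[TrainConfig] = None,
) -> float:
    """Agreement (Cronbach's alpha) of window probabilities across a grid.

    Each grid point is a dict of overrides: TrainConfig fields (``lr``,
    ``epochs``, ``batch_size``) and/or ``pool`` (per-layer pooling factors).
    One model is trained per point and all models score the same window grid
    on ``rec``; high alpha means the detector is insensitive to moderate
    hyperparameter perturbations.
    """
    if len(grid) < 2:
        raise ParameterError("sensitivity grid needs at least two points")
    base = base_config or TrainConfig(seed=seed)
    rows = []
    for point in grid:
        point = dict(point)
        pool = point.pop("pool", None)
        cfg = TrainConfig(**{**asdict(base), **point})
        spec = ArchitectureSpec(fs=rec.fs) if pool is None else ArchitectureSpec(
            fs=rec.fs, pool=tuple(pool)
        )
        model = build_model(spec, seed=seed)
        train(model, ts, cfg)
        rows.append(predict_windows(model, rec).probs.ravel())
    return cronbach_alpha(np.vstack(rows))


# ---------------------------------------------------------------- checkpoint


def save_model(model: DetectorModel, path: str) -> None:
    """Self-describing checkpoint: architecture + weights + training config."""
    header = {
        "arch": model.arch.to_dict(),
        "train_config": asdict(model.train_config) if model.train_config else None,
        "provenance": model.provenance,
        "trained": model.trained,
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params())}
    np.savez(path, header=json.dumps(header), **arrays)


def load_model(path: str) -> DetectorModel:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        arch = ArchitectureSpec(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in header["arch"].items()})
        model = build_model(arch, seed=0)
        params = model.net.params()
        for i, p in enumerate(params):
            p[...] = z[f"p{i}"]
    if header["train_config"]:
        model.train_config = TrainConfig(**header["train_config"])
    model.provenance = header["provenance"]
    model.trained = header["trained"]
    return model
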