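"""Surrogate sleep recordings with ground truth.

The generator reproduces the statistical structure of NREM sleep recordings
used to validate the detectors: 11-15 Hz spindle bursts of 0.5-3 s (flat or
waxing/waning envelope) embedded in white / pink (1/f) / Brownian (1/f^2)
noise, optional 4-8 Hz theta distractors, phase-randomised broadband
artifacts, and multichannel rotating-wave spindles on electrode montages.

A spindle is the real part of ``A * exp(i*(w*t + theta0))`` times its
envelope; a rotating wave on electrodes with polar angles ``theta_n`` is the
real part of ``A * exp(i*(w*t - gamma*theta_n)) + sigma*eta(t)`` with
``eta`` Gaussian white noise and ``gamma`` the polar wavenumber.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError
from .recording import Recording

__all__ = [
    "ManifestEntry",
    "GroundTruthManifest",
    "WaveConfig",
    "simulate_spindle",
    "generate_noise",
    "phase_randomize",
    "make_artifact_templates",
    "simulate_recording",
    "simulate_rotating_wave",
    "rotating_wave_recording",
    "montage_polar_angles",
    "TEN_TWENTY_19",
    "TEN_TWENTY_64",
]

SPINDLE_BAND = (11.0, 15.0)
THETA_BAND = (4.0, 8.0)

#: the classic 19-electrode international 10-20 montage
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

#: a standard 64-channel extension (10-10 positions)
TEN_TWENTY_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P9", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
]


# ------------------------------------------------------------------ manifest


@dataclass(frozen=True)
class ManifestEntry:
    channel_id: str
    t_start: float
    t_end: float
    kind: str                  # spindle | theta | artifact
    omega: float               # rad/s (0 for artifacts)
    theta0: float              # initial phase, rad
    amplitude: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class GroundTruthManifest:
    """The simulator's true event table."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def of_kind(self, kind: str) -> "GroundTruthManifest":
        return GroundTruthManifest([e for e in self.entries if e.kind == kind])

    def spindles(self) -> "GroundTruthManifest":
        return self.of_kind("spindle")

    def for_channel(self, channel_id: str) -> "GroundTruthManifest":
        return GroundTruthManifest([e for e in self.entries if e.channel_id == channel_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.channel_id, e.t_start, e.t_end, e.kind, e.omega, e.theta0, e.amplitude)
                for e in self.entries
            ],
            columns=["channel", "t_start", "t_end", "kind", "omega", "theta0", "amplitude"],
        )

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_tsv(cls, path: str) -> "GroundTruthManifest":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                ManifestEntry(
                    str(r.channel), float(r.t_start), float(r.t_end), str(r.kind),
                    float(r.omega), float(r.theta0), float(r.amplitude),
                )
                for r in df.itertuples()
            ]
        )


@dataclass
class WaveConfig:
    """Configuration of one rotating-wave segment (see module docstring)."""

    A: float = 1.0
    omega: float = 2 * np.pi * 13.0     # rad/s
    gamma: int = 1                      # polar wavenumber; +1/0/-1 in the experiments
    sigma: float = 0.0                  # white-noise scale
    theta_n: np.ndarray = field(default_factory=lambda: np.zeros(1))
    n_samples: int = 100
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.theta_n = np.asarray(self.theta_n, dtype=float)
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")
        if self.n_samples < 1 or self.fs <= 0:
            raise ParameterError("need n_samples >= 1 and fs > 0")


# ------------------------------------------------------------------ signals


def simulate_spindle(
    A: float,
    f: float,
    theta0: float,
    duration: float,
    fs: float,
    envelope: str = "waxing_waning",
) -> np.ndarray:
    """One oscillatory burst: ``A*cos(2*pi*f*t + theta0)`` times an envelope.

    ``envelope='flat'`` gives the constant-amplitude burst used in the
    amplitude-control experiment; ``'waxing_waning'`` applies a Hann window,
    the standard spindle rise-and-fall profile.
    """
    if duration <= 0 or fs <= 0:
        raise ParameterError("duration and fs must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = A * np.cos(2 * np.pi * f * t + theta0)
    if envelope == "flat":
        return x
    if envelope == "waxing_waning":
        return x * np.hanning(n)
    raise ParameterError(f"unknown envelope {envelope!r}")


_NOISE_EXPONENT = {"white": 0.0, "pink": 1.0, "brownian": 2.0}


def generate_noise(
    kind: str,
    n: int,
    fs: float,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Colored Gaussian noise with RMS ``scale``.

    The log-log PSD slope is 0 (white), -1 (pink) or -2 (brownian); colored
    kinds are produced by spectral shaping of white noise, which makes the
    slope exact in expectation and the output stationary.
    """
    if kind not in _NOISE_EXPONENT:
        raise ParameterError(f"unknown noise kind {kind!r}; expected {list(_NOISE_EXPONENT)}")
    if n < 256:
        raise ParameterError("need at least 256 samples for a stable spectrum")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = rng.standard_normal(n)
    beta = _NOISE_EXPONENT[kind]
    if beta > 0:
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1 / fs)
        shaping = np.zeros_like(f)
        shaping[1:] = f[1:] ** (-beta / 2)
        x = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms)


def phase_randomize(template: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Surrogate with the template's exact amplitude spectrum and random phases.

    Phases of all positive non-Nyquist frequencies are drawn uniformly from
    [0, 2*pi); the DC term is kept and, for even lengths, the Nyquist term
    keeps its magnitude with a random sign, so the output is exactly real.
    """
    x = np.asarray(template, dtype=float)
    n = x.size
    if n < 16:
        raise ParameterError("template too short to phase-randomise (need >= 16 samples)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    phases = np.zeros(mag.shape)
    hi = mag.size - 1 if n % 2 == 0 else mag.size
    phases[1:hi] = rng.uniform(0, 2 * np.pi, hi - 1)
    out_spec = mag * np.exp(1j * phases)
    out_spec[0] = spec[0]
    if n % 2 == 0:
        out_spec[-1] = mag[-1] * rng.choice([-1.0, 1.0])
    return np.fft.irfft(out_spec, n)


def make_artifact_templates(fs: float) -> list[np.ndarray]:
    """Parametric broadband-transient templates (damped chirp and step).

    The instances injected into surrogates are phase-randomised draws from
    these templates, mimicking artifact libraries built from real recordings.
    Real artifact libraries are built from transients that amplitude
    thresholding mistakes for spindles, so the templates are long enough
    (~1 s) and carry enough 8-20 Hz energy to sustain a high narrow-band
    envelope, while remaining broadband (low band-power *ratio*).
    """
    from scipy.signal import chirp

    t1 = np.arange(int(round(1.2 * fs))) / fs
    damped_chirp = chirp(t1, f0=24.0, f1=6.0, t1=t1[-1] if len(t1) > 1 else 1.2) * np.exp(
        -t1 / 0.5
    )

    t2 = np.arange(int(round(1.0 * fs))) / fs
    edge = 1.0 / (1.0 + np.exp(-(t2 - 0.05) / 0.004))
    step = edge * np.exp(-np.maximum(t2 - 0.05, 0) / 0.3)

    # sustained broadband burst (EMG/movement-like); fixed internal seed so the
    # template itself is deterministic -- instances vary via phase_randomize
    t3 = np.arange(int(round(1.0 * fs))) / fs
    taper = 1.0 / (1.0 + np.exp(-(t3 - 0.08) / 0.02))
    taper *= taper[::-1]
    burst = np.random.default_rng(1234).standard_normal(len(t3)) * taper

    templates = [damped_chirp, step, burst]
    return [t / np.sqrt(np.mean(t**2)) for t in templates]


# ----------------------------------------------------------- full recordings


def _place_events(
    rng: np.random.Generator,
    duration_s: float,
    n_events: int,
    durations: np.ndarray,
    occupied: list[tuple[float, float]],
    guard: float,
    max_retries: int,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping intervals with a guard gap."""
    placed: list[tuple[float, float]] = []
    retries = 0
    for d in durations:
        while True:
            if retries > max_retries:
                raise PlacementError(
                    f"could not place {n_events} events of ~{np.mean(durations):.2f} s "
                    f"into {duration_s:.0f} s after {max_retries} retries"
                )
            t0 = rng.uniform(0.0, duration_s - d)
            t1 = t0 + d
            if all(t1 + guard <= a or b + guard <= t0 for a, b in occupied):
                occupied.append((t0, t1))
                placed.append((t0, t1))
                break
            retries += 1
    return placed


def simulate_recording(
    n_channels: int,
    duration_min: float,
    spindle_rate: float = 2.0,
    noise: Sequence[tuple[str, float]] = (("white", 0.25),),
    theta_rate: float = 0.0,
    artifact_rate: float = 0.0,
    artifact_templates: Optional[Sequence[np.ndarray]] = None,
    artifact_amplitude: float = 1.0,
    amplitude: float = 1.0,
    envelope: str = "waxing_waning",
    freq_range: tuple[float, float] = SPINDLE_BAND,
    duration_range: tuple[float, float] = (0.5, 3.0),
    fs: float = 200.0,
    seed: int = 0,
    guard: float = 0.05,
    max_retries: int = 10_000,
) -> tuple[Recording, GroundTruthManifest]:
    """Multichannel surrogate recording plus its ground-truth manifest.

    Event counts per channel are Poisson with mean ``rate * duration``
    (conditioned on non-overlapping placement with a 50 ms guard gap);
    spindle frequencies are uniform over ``freq_range`` and initial phases
    uniform over [0, 2*pi). Theta distractors draw 4-8 Hz frequencies and
    400-1000 ms durations; artifacts are phase-randomised template instances.
    """
    if spindle_rate < 0 or theta_rate < 0 or artifact_rate < 0:
        raise ParameterError("rates must be non-negative")
    duration_s = duration_min * 60.0
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_channels, n))
    entries: list[ManifestEntry] = []

    if artifact_rate > 0 and artifact_templates is None:
        artifact_templates = make_artifact_templates(fs)

    for c in range(n_channels):
        for kind, rms in noise:
            data[c] += generate_noise(kind, n, fs, scale=rms, seed=rng)
        occupied: list[tuple[float, float]] = []

        specs: list[tuple[str, float]] = []   # (kind, rate)
        for kind, rate in (("spindle", spindle_rate), ("theta", theta_rate), ("artifact", artifact_rate)):
            if rate > 0:
                specs.append((kind, rate))
        for kind, rate in specs:
            count = rng.poisson(rate * duration_min)
            if count == 0:
                continue
            if kind == "spindle":
                durs = rng.uniform(*duration_range, size=count)
            elif kind == "theta":
                durs = rng.uniform(0.4, 1.0, size=count)
            else:
                tmpl_idx = rng.integers(0, len(artifact_templates), size=count)
                durs = np.array([len(artifact_templates[i]) / fs for i in tmpl_idx])
            slots = _place_events(rng, duration_s, count, durs, occupied, guard, max_retries)
            for j, (t0, t1) in enumerate(slots):
                i0 = int(round(t0 * fs))
                if kind == "artifact":
                    tmpl = artifact_templates[tmpl_idx[j]]
                    wav = phase_randomize(tmpl, rng) * artifact_amplitude
                    omega, theta0, amp = 0.0, 0.0, artifact_amplitude
                else:
                    f = rng.uniform(*(freq_range if kind == "spindle" else THETA_BAND))
                    theta0 = rng.uniform(0, 2 * np.pi)
                    amp = amplitude
                    env = envelope if kind == "spindle" else "waxing_waning"
                    wav = simulate_spindle(amp, f, theta0, t1 - t0, fs, envelope=env)
                    omega = 2 * np.pi * f
                data[c, i0 : i0 + len(wav)] += wav[: n - i0]
                entries.append(
                    ManifestEntry(f"ch{c:02d}", t0, t0 + len(wav) / fs, kind, omega, theta0, amp)
                )

    rec = Recording(
        data,
        fs,
        [f"ch{c:02d}" for c in range(n_channels)],
        meta={"generator": "simulate_recording", "seed": seed},
    )
    entries.sort(key=lambda e: (e.channel_id, e.t_start))
    return rec, GroundTruthManifest(entries)


# ------------------------------------------------------------ rotating waves


def simulate_rotating_wave(cfg: WaveConfig, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multichannel rotating-wave segment, shape (n_channels, n_samples).

    Channel ``n`` carries ``Re[A * exp(i*(omega*t - gamma*theta_n))]`` plus
    ``sigma`` times Gaussian white noise. With ``sigma=0`` the analytic phase
    offset between channels n and m is ``-gamma*(theta_n - theta_m)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(cfg.n_samples) / cfg.fs
    phase = cfg.omega * t[None, :] - cfg.gamma * cfg.theta_n[:, None]
    x = cfg.A * np.cos(phase)
    if cfg.sigma > 0:
        x = x + cfg.sigma * rng.standard_normal(x.shape)
    return x


def rotating_wave_recording(
    cfg: WaveConfig,
    seed: int | np.random.Generator = 0,
    channel_ids: Optional[list[str]] = None,
) -> Recording:
    """`simulate_rotating_wave` wrapped into a Recording with polar angles."""
    data = simulate_rotating_wave(cfg, seed)
    ids = channel_ids or [f"e{i:02d}" for i in range(len(cfg.theta_n))]
    return Recording(data, cfg.fs, ids, polar_angle=cfg.theta_n)


def montage_polar_angles(
    montage: str = "ten_twenty",
    coords: Optional[np.ndarray] = None,
) -> tuple[list[str], np.ndarray]:
    """Electrode polar angles with respect to the anterior sagittal midline.

    The angle of an electrode at head position (x right, y anterior, z up) is
    the azimuth about the vertex axis, ``atan2(x, y)``: 0 for anterior midline
    electrodes, +pi/2 right-lateral, -pi/2 left-lateral, +-pi posterior. This
    is the polar convention of the standard top-view 10-20 layout.

    Montages: ``ten_twenty`` (classic 19 electrodes), ``ten_twenty_64``
    (10-10 extension), ``grid_10x10`` (100 angles sweeping the circle
    monotonically), ``custom`` (supply ``coords`` of shape (n, 2) view-plane
    points or (n, 3) head positions).

    Returns (names, angles in radians within [-pi, pi]).
    """
    if montage in ("ten_twenty", "ten_twenty_64"):
        import mne

        mne.set_log_level("ERROR")
        pos = mne.channels.make_standard_montage("standard_1020").get_positions()["ch_pos"]
        names = TEN_TWENTY_19 if montage == "ten_twenty" else TEN_TWENTY_64
        p = np.array([pos[ch] for ch in names])
        return list(names), np.arctan2(p[:, 0], p[:, 1])
    if montage == "grid_10x10":
        k = np.arange(100)
        theta = -np.pi + 2 * np.pi * (k + 0.5) / 100
        return [f"g{i:02d}" for i in k], theta
    if montage == "custom":
        if coords is None:
            raise ParameterError("custom montage requires coords")
        p = np.asarray(coords, dtype=float)
        if p.ndim != 2 or p.shape[1] not in (2, 3):
            raise ParameterError("coords must be (n, 2) or (n, 3)")
        theta = np.arctan2(p[:, 0], p[:, 1]) if p.shape[1] == 3 else np.arctan2(p[:, 1], p[:, 0])
        return [f"c{i:02d}" for i in range(len(theta))], theta
    raise ParameterError(f"unknown montage {montage!r}")
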