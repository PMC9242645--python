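"""Shared fixtures: small surrogates and one session-scoped trained pipeline."""
import numpy as np
import pytest

import spindlekit as sk


@pytest.fixture(scope="session")
def white_surrogate():
    """10 min x 10 channels, 2 spindles/min, white noise -- the standard
    end-to-end study condition."""
    rec, manifest = sk.simulate_recording(
        10, 10.0, spindle_rate=2.0, noise=[("white", 0.25)],
        envelope="waxing_waning", fs=200, seed=101,
    )
    return rec, manifest


@pytest.fixture(scope="session")
def white_pipeline(white_surrogate):
    """Full SNR-bootstrapped CNN pipeline on the white-noise surrogate."""
    rec, manifest = white_surrogate
    result = sk.bootstrap_cnn(rec, seed=101, train_config=sk.TrainConfig(seed=101, epochs=8))
    return rec, manifest, result


@pytest.fixture(scope="session")
def toy_model():
    """A detector trained on a separable-by-construction toy set at fs=128.

    Positives are 13 Hz tones with random phase/amplitude, negatives white
    noise; held out windows are classified near perfectly, which makes the
    model useful for interpretation (saliency / feature map) tests.
    """
    fs = 128.0
    win = 64
    rng = np.random.default_rng(3)
    n_per = 120
    t = np.arange(win) / fs
    pos = np.stack([
        np.cos(2 * np.pi * 13.0 * t + rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 2.0)
        + 0.1 * rng.standard_normal(win)
        for _ in range(n_per)
    ])
    neg = rng.standard_normal((n_per, win))
    ts = sk.TrainingSet(
        windows=np.vstack([pos, neg]),
        labels=np.array([1] * n_per + [0] * n_per),
        channel_ids=["c0"] * (2 * n_per),
        t_starts=np.zeros(2 * n_per),
        fs=fs,
    )
    model = sk.build_model(sk.ArchitectureSpec(fs=fs), seed=3)
    sk.train(model, ts, sk.TrainConfig(seed=3, epochs=10))
    return model, ts


@pytest.fixture(scope="session")
def toy_model_1k():
    """As toy_model but at fs=1000, where the deepest feature map still has
    ~33 ms resolution and can resolve individual oscillation cycles."""
    fs = 1000.0
    win = 500
    rng = np.random.default_rng(6)
    n_per = 80
    t = np.arange(win) / fs
    pos = np.stack([
        np.cos(2 * np.pi * 13.0 * t + rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 2.0)
        + 0.1 * rng.standard_normal(win)
        for _ in range(n_per)
    ])
    neg = rng.standard_normal((n_per, win))
    ts = sk.TrainingSet(
        windows=np.vstack([pos, neg]),
        labels=np.array([1] * n_per + [0] * n_per),
        channel_ids=["c0"] * (2 * n_per),
        t_starts=np.zeros(2 * n_per),
        fs=fs,
    )
    model = sk.build_model(sk.ArchitectureSpec(fs=fs), seed=6)
    sk.train(model, ts, sk.TrainConfig(seed=6, epochs=6))
    return model, ts
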