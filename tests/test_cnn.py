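"""Detector model: architecture contracts, training, inference, interpretation."""
import numpy as np
import pytest

import spindlekit as sk
from spindlekit.cnn import cronbach_alpha
from spindlekit.errors import ArchitectureError, ParameterError, TrainingError


class TestArchitecture:
    def test_default_forward_softmax_normalised(self):
        model = sk.build_model(sk.ArchitectureSpec(fs=1000.0), seed=0)
        probs = model.predict_proba(np.zeros((3, 500)))
        assert probs.shape == (3,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_kernel_ms_autoscale_across_fs(self):
        spec = sk.ArchitectureSpec(fs=200.0)
        assert spec.input_samples == 100
        assert spec.kernel_samples()[0] == 18    # 90 ms at 200 Hz
        model = sk.build_model(spec, seed=0)
        assert model.predict_proba(np.zeros((1, 100))).shape == (1,)

    def test_pooling_collapse_names_layer(self):
        # 100 -> 25 -> 6 -> 1 -> 0: the chain collapses at the fourth block
        with pytest.raises(ArchitectureError, match="layer 4"):
            sk.ArchitectureSpec(fs=200.0, pool=(4, 4, 4, 4, 4))

    def test_parameter_count_deterministic(self):
        a = sk.build_model(sk.ArchitectureSpec(fs=200.0), seed=1)
        b = sk.build_model(sk.ArchitectureSpec(fs=200.0), seed=1)
        assert a.weights_digest() == b.weights_digest()
        assert [p.shape for p in a.net.params()] == [p.shape for p in b.net.params()]


class TestTraining:
    def test_separable_toy_set_high_heldout_accuracy(self, toy_model):
        model, ts = toy_model
        probs = model.predict_proba(ts.windows)
        acc = np.mean((probs >= 0.5).astype(int) == ts.labels)
        assert acc >= 0.95
        assert model.history["val_loss"][-1] < model.history["val_loss"][0]

    def test_training_is_deterministic(self):
        fs = 128.0
        rng = np.random.default_rng(0)
        t = np.arange(64) / fs
        wins = np.vstack([
            np.stack([np.cos(2 * np.pi * 13 * t + p) for p in rng.uniform(0, 6, 40)]),
            rng.standard_normal((40, 64)),
        ])
        ts = sk.TrainingSet(wins, np.array([1] * 40 + [0] * 40), ["c"] * 80, np.zeros(80), fs)
        digests = []
        for _ in range(2):
            m = sk.build_model(sk.ArchitectureSpec(fs=fs), seed=9)
            sk.train(m, ts, sk.TrainConfig(seed=9, epochs=3))
            digests.append(m.weights_digest())
        assert digests[0] == digests[1]

    def test_single_class_rejected(self):
        fs = 128.0
        wins = np.random.default_rng(0).standard_normal((20, 64))
        ts = sk.TrainingSet(wins, np.ones(20, dtype=int), ["c"] * 20, np.zeros(20), fs)
        m = sk.build_model(sk.ArchitectureSpec(fs=fs), seed=0)
        with pytest.raises(TrainingError):
            sk.train(m, ts)


class TestInference:
    def test_window_grid_arithmetic(self):
        model = sk.build_model(sk.ArchitectureSpec(fs=1000.0), seed=0)
        rec = sk.Recording(np.zeros((1, 10_000)), 1000.0, ["c0"])
        preds = sk.predict_windows(model, rec)
        assert len(preds.starts) == 96
        assert preds.starts[0] == 0.0 and preds.starts[-1] == pytest.approx(9.5)

    def test_duplicated_channel_identical_predictions(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(600)
        model = sk.build_model(sk.ArchitectureSpec(fs=200.0), seed=0)
        rec = sk.Recording(np.stack([x, x]), 200.0, ["a", "b"])
        preds = sk.predict_windows(model, rec)
        np.testing.assert_array_equal(preds.probs[0], preds.probs[1])

    def test_constant_input_constant_probabilities(self):
        model = sk.build_model(sk.ArchitectureSpec(fs=200.0), seed=0)
        rec = sk.Recording(np.zeros((1, 1000)), 200.0, ["a"])
        preds = sk.predict_windows(model, rec)
        assert np.ptp(preds.probs) == pytest.approx(0.0, abs=1e-12)

    def test_too_short_recording(self):
        model = sk.build_model(sk.ArchitectureSpec(fs=200.0), seed=0)
        with pytest.raises(ParameterError):
            sk.predict_windows(model, sk.Recording(np.zeros((1, 50)), 200.0, ["a"]))


class TestInterpretation:
    def test_saliency_concentrates_on_spindle_half(self, toy_model):
        model, ts = toy_model
        fs, win = 128.0, 64
        rng = np.random.default_rng(5)
        t = np.arange(win // 2) / fs
        half = np.concatenate([
            0.3 * rng.standard_normal(win // 2),
            np.cos(2 * np.pi * 13 * t) + 0.1 * rng.standard_normal(win // 2),
        ])
        g = sk.saliency_map(model, half, times_input=True)
        assert len(g) == win
        assert g[win // 2 :].mean() > g[: win // 2].mean()

    def test_saliency_prefers_larger_amplitude_spindle(self, toy_model):
        model, _ = toy_model
        fs, win = 128.0, 64
        t = np.arange(win // 2) / fs
        two = np.concatenate([
            0.4 * np.cos(2 * np.pi * 13 * t),
            2.0 * np.cos(2 * np.pi * 13 * t),
        ])
        g = sk.saliency_map(model, two, times_input=True)
        assert g[win // 2 :].mean() > g[: win // 2].mean()

    def test_saliency_of_untrained_model_warns(self):
        model = sk.build_model(sk.ArchitectureSpec(fs=128.0), seed=0)
        with pytest.warns(UserWarning):
            g = sk.saliency_map(model, np.zeros(64))
        assert g.shape == (64,) and np.all(np.isfinite(g))

    def test_feature_map_shapes_and_nonnegativity(self, toy_model):
        model, _ = toy_model
        maps = sk.feature_maps(model, np.zeros(64))
        assert [m.shape[0] for m in maps] == [32, 64, 128, 192, 256]
        assert all((m >= 0).all() for m in maps)

    def test_last_layer_activations_track_oscillation_cycles(self, toy_model_1k):
        """Peaks of the strongest last-conv feature recur roughly once per cycle."""
        model, _ = toy_model_1k
        fs, win = 1000.0, 500
        t = np.arange(win) / fs
        x = np.cos(2 * np.pi * 13 * t)
        last = sk.feature_maps(model, x)[-1]
        # count activation peaks of the most energetic filter across the map
        f = last[np.argmax(last.sum(axis=1))]
        n_cycles = 13 * win / fs
        n_peaks = ((f[1:-1] > f[:-2]) & (f[1:-1] >= f[2:]) & (f[1:-1] > 0)).sum() + (
            1 if f[0] > f[1] and f[0] > 0 else 0
        ) + (1 if f[-1] > f[-2] and f[-1] > 0 else 0)
        assert abs(n_peaks - n_cycles) <= max(1.0, 0.5 * n_cycles)


class TestCronbach:
    def test_identical_items_give_one(self):
        m = np.tile(np.random.default_rng(0).uniform(size=200), (4, 1))
        assert cronbach_alpha(m) == pytest.approx(1.0, abs=1e-9)

    def test_independent_items_give_zero(self):
        rng = np.random.default_rng(1)
        alphas = [cronbach_alpha(rng.uniform(size=(4, 300))) for _ in range(100)]
        assert abs(np.mean(alphas)) < 0.1

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ParameterError):
            cronbach_alpha(np.zeros((1, 10)))


def test_hyperparameter_sensitivity_high_on_clean_surrogate():
    rec, _ = sk.simulate_recording(2, 3.0, spindle_rate=3.0, fs=200, seed=31)
    events, traces = sk.snr_events(rec)
    ts = sk.build_training_set(rec, events, traces, seed=31)
    grid = [{"lr": 1e-3, "epochs": 5}, {"lr": 1.4e-3, "epochs": 7}]
    alpha = sk.hyperparameter_sensitivity(ts, rec, grid, seed=31)
    assert alpha > 0.9


class TestCheckpoint:
    def test_round_trip_bitfaithful(self, toy_model, tmp_path):
        model, ts = toy_model
        path = str(tmp_path / "m.npz")
        sk.save_model(model, path)
        back = sk.load_model(path)
        assert back.weights_digest() == model.weights_digest()
        assert back.trained
        np.testing.assert_array_equal(
            back.predict_proba(ts.windows[:8]), model.predict_proba(ts.windows[:8])
        )
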