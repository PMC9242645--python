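"""Validation analyses: scoring, extent, rates, participation, rotation."""
import itertools

import numpy as np
import pytest

import spindlekit as sk
from spindlekit.errors import ParameterError
from spindlekit.simulate import GroundTruthManifest, ManifestEntry


def ev(ch, a, b, det="CNN", score=1.0):
    return sk.SpindleEvent(ch, a, b, score, det)


def truth(ch, a, b):
    return ManifestEntry(ch, a, b, "spindle", 2 * np.pi * 13, 0.0, 1.0)


# ------------------------------------------------------------------ scoring


def exhaustive_best_matching(events, truths, min_overlap=0.5):
    """Oracle: enumerate all one-to-one assignments, maximise cardinality
    (ties broken by total overlap)."""

    def eligible(e, t):
        ovl = max(0.0, min(e.t_end, t.t_end) - max(e.t_start, t.t_start))
        shorter = min(e.duration, t.t_end - t.t_start)
        return ovl if e.channel_id == t.channel_id and shorter > 0 and ovl >= min_overlap * shorter - 1e-12 else None

    best = (0, 0.0)
    idx_t = list(range(len(truths)))
    for k in range(min(len(events), len(truths)), -1, -1):
        for e_subset in itertools.combinations(range(len(events)), k):
            for t_perm in itertools.permutations(idx_t, k):
                total = 0.0
                ok = True
                for i, j in zip(e_subset, t_perm):
                    o = eligible(events[i], truths[j])
                    if o is None:
                        ok = False
                        break
                    total += o
                if ok:
                    best = max(best, (k, total))
        if best[0] == k and k > 0:
            break
    return best[0]


class TestScoreDetection:
    def test_perfect_detection(self):
        truths = [truth("a", 0, 1), truth("a", 5, 6), truth("b", 2, 3)]
        events = [ev("a", 0, 1), ev("a", 5, 6), ev("b", 2, 3)]
        assert sk.score_detection(events, GroundTruthManifest(truths)) == (1.0, 1.0, 1.0)

    def test_empty_events_zero_recall(self):
        truths = GroundTruthManifest([truth("a", 0, 1)])
        p, r, f1 = sk.score_detection([], truths)
        assert (r, f1) == (0.0, 0.0)

    def test_half_overlap_rule(self):
        truths = GroundTruthManifest([truth("a", 0.0, 1.0)])
        # 0.5 s overlap on a 1 s truth, event 1 s long: exactly 50% -> match
        assert sk.score_detection([ev("a", 0.5, 1.5)], truths)[1] == 1.0
        # 0.4 s overlap: below 50% of the shorter -> no match
        assert sk.score_detection([ev("a", 0.6, 1.6)], truths)[1] == 0.0

    def test_agrees_with_exhaustive_matching_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n_e, n_t = rng.integers(0, 6, 2)
            events = [
                ev("a", s, s + d)
                for s, d in zip(rng.uniform(0, 8, n_e), rng.uniform(0.5, 2.0, n_e))
            ]
            truths = [
                truth("a", s, s + d)
                for s, d in zip(rng.uniform(0, 8, n_t), rng.uniform(0.5, 2.0, n_t))
            ]
            p, r, _ = sk.score_detection(events, GroundTruthManifest(truths))
            tp = exhaustive_best_matching(events, truths)
            assert p == pytest.approx(tp / n_e if n_e else 0.0)
            assert r == pytest.approx(tp / n_t if n_t else 0.0)


# ------------------------------------------------------------------- extent


class TestExtent:
    def test_class_boundaries(self):
        assert sk.ExtentClass.classify(1) == "local"
        assert sk.ExtentClass.classify(2) == "local"
        assert sk.ExtentClass.classify(3) == "regional"
        assert sk.ExtentClass.classify(10) == "regional"
        assert sk.ExtentClass.classify(11) == "multi_area"

    def test_two_channels_local(self):
        classes = sk.classify_extent([ev("a", 0, 0.5), ev("b", 0, 0.5)])
        assert {c.label for c in classes} == {"local"}

    def test_three_and_eleven_channels(self):
        evs = [ev(f"c{i}", 0, 0.5) for i in range(3)]
        assert {c.label for c in sk.classify_extent(evs)} == {"regional"}
        evs = [ev(f"c{i}", 0, 0.5) for i in range(11)]
        assert {c.label for c in sk.classify_extent(evs)} == {"multi_area"}

    def test_event_evolving_from_local_to_multi_area(self):
        evs = [ev("c0", 0.0, 3.0)] + [ev(f"c{i}", 2.0, 3.0) for i in range(1, 13)]
        classes = {c.t_start: c.label for c in sk.classify_extent(evs)}
        assert classes[0.0] == "local"
        assert classes[2.0] == "multi_area"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        evs = [ev(f"c{i}", rng.uniform(0, 4), rng.uniform(5, 8)) for i in range(6)]
        a = sk.classify_extent(evs)
        b = sk.classify_extent(list(reversed(evs)))
        assert a == b


# ----------------------------------------------------------------- rates


class TestRates:
    def test_simultaneous_event_counted_once(self):
        evs = [ev(f"c{i}", 10.0, 11.0) for i in range(5)]
        assert sk.multi_electrode_rate(evs, 10.0) == pytest.approx(0.1)
        single_electrode_rate = len(evs) / 10.0
        assert single_electrode_rate == pytest.approx(0.5)

    def test_overlap_chain_is_one_component(self):
        evs = [ev("a", 0.0, 1.0), ev("b", 0.8, 2.0), ev("c", 1.8, 3.0)]  # a-b, b-c, not a-c
        groups = sk.array_level_events(evs)
        assert len(groups) == 1

    def test_components_match_graph_oracle(self):
        rng = np.random.default_rng(3)
        evs = [
            ev(f"c{i % 4}", s, s + d)
            for i, (s, d) in enumerate(zip(rng.uniform(0, 20, 15), rng.uniform(0.5, 2, 15)))
        ]
        # oracle: BFS over the pairwise-overlap graph
        n = len(evs)
        adj = {i: [] for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if min(evs[i].t_end, evs[j].t_end) - max(evs[i].t_start, evs[j].t_start) > 1e-9:
                    adj[i].append(j)
                    adj[j].append(i)
        seen, n_comp = set(), 0
        for i in range(n):
            if i in seen:
                continue
            n_comp += 1
            stack = [i]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(adj[u])
        assert len(sk.array_level_events(evs)) == n_comp

    def test_multi_electrode_rate_never_exceeds_single_electrode_rate(self):
        rng = np.random.default_rng(4)
        evs = [
            ev(f"c{rng.integers(0, 5)}", s, s + d)
            for s, d in zip(rng.uniform(0, 60, 30), rng.uniform(0.5, 2, 30))
        ]
        assert sk.multi_electrode_rate(evs, 1.0) <= len(evs) / 1.0


class TestRegionParticipation:
    labels = {f"c{i}": region for i, region in enumerate("ABCDE")}

    def test_three_of_five_regions(self):
        evs = [ev("c0", 0, 1), ev("c1", 0.2, 1.2), ev("c2", 0.4, 1.4)]
        assert sk.region_participation(evs, self.labels) == [60.0]

    def test_all_channels_hundred_percent(self):
        evs = [ev(f"c{i}", 0, 1) for i in range(5)]
        assert sk.region_participation(evs, self.labels) == [100.0]

    def test_single_channel_in_seven_region_montage(self):
        labels = {f"c{i}": f"R{i}" for i in range(7)}
        out = sk.region_participation([ev("c3", 0, 1)], labels)
        assert out == [pytest.approx(100 / 7)]

    def test_missing_labels_rejected(self):
        with pytest.raises(ParameterError):
            sk.region_participation([ev("zz", 0, 1)], self.labels)


# ------------------------------------------------------------ rotating waves


class TestRotationIndices:
    names, theta = sk.montage_polar_angles("ten_twenty")

    def wave_rec(self, gamma, omega=2 * np.pi * 13.0, theta0=0.0, sigma=0.0, seed=0):
        cfg = sk.WaveConfig(omega=omega, gamma=gamma, sigma=sigma, theta_n=self.theta,
                            n_samples=1000, fs=1000.0)
        rec = sk.rotating_wave_recording(cfg, seed=seed)
        if theta0:
            t = np.arange(cfg.n_samples) / cfg.fs
            rec = rec.with_data(np.cos(omega * t[None, :] - gamma * self.theta[:, None] + theta0))
        return rec

    def test_forward_wave_aligned_index_near_unity(self):
        rr = sk.rotation_indices(self.wave_rec(+1), 0.0, 1.0)
        assert rr.mean_aligned > 0.99
        assert 0.0 <= rr.mean_anti <= 1.0

    def test_reversed_wave_swaps_indices(self):
        fwd = sk.rotation_indices(self.wave_rec(+1), 0.0, 1.0)
        rev = sk.rotation_indices(self.wave_rec(-1), 0.0, 1.0)
        assert rev.mean_anti == pytest.approx(fwd.mean_aligned, abs=0.02)
        assert rev.mean_aligned == pytest.approx(fwd.mean_anti, abs=0.02)

    def test_global_phase_invariance(self):
        a = sk.rotation_indices(self.wave_rec(+1, theta0=0.0), 0.0, 1.0)
        b = sk.rotation_indices(self.wave_rec(+1, theta0=1.3), 0.0, 1.0)
        assert b.mean_aligned == pytest.approx(a.mean_aligned, abs=0.02)
        assert b.mean_anti == pytest.approx(a.mean_anti, abs=0.02)

    def test_indices_bounded(self):
        rr = sk.rotation_indices(self.wave_rec(+1, sigma=0.5, seed=4), 0.0, 1.0)
        for arr in (rr.alpha_aligned_t, rr.alpha_anti_t):
            assert np.all((arr >= 0) & (arr <= 1 + 1e-12))

    def test_too_few_channels_rejected(self):
        rec = sk.Recording(np.zeros((2, 1000)), 1000.0, ["a", "b"],
                           polar_angle=np.array([0.0, 1.0]))
        with pytest.raises(ParameterError):
            sk.rotation_indices(rec, 0.0, 1.0)


# ------------------------------------------------- PSD / time-shifted average


class TestWelchContrast:
    def test_insufficient_events_rejected(self, white_surrogate):
        rec, _ = white_surrogate
        with pytest.raises(ParameterError):
            sk.welch_contrast(rec, [ev("ch00", 0, 1)])

    def test_pure_noise_events_give_no_contrast(self):
        rec, _ = sk.simulate_recording(1, 8.0, spindle_rate=0.0, fs=200, seed=9)
        rng = np.random.default_rng(0)
        fake = []
        t = 1.0
        while len(fake) < 30:
            fake.append(ev("ch00", t, t + 1.0))
            t += 12.0
        freqs, ps, pn = sk.welch_contrast(rec, fake, seed=1)
        band = (freqs >= 11) & (freqs <= 15)
        contrast_db = 10 * np.log10(ps[band] / pn[band])
        assert np.abs(contrast_db.mean()) < 1.5


class TestTimeShiftedAverage:
    def test_average_of_identical_copies_is_the_waveform(self):
        fs = 200.0
        n = int(60 * fs)
        x = np.zeros(n)
        hw = int(0.5 * fs)
        tmpl = np.hanning(2 * hw + 1) * np.cos(2 * np.pi * 13 * np.arange(2 * hw + 1) / fs)
        tmpl[hw] = tmpl.max() + 0.5   # unique positive peak at the centre
        events = []
        for k in range(25):
            i0 = int((2 + 2.3 * k) * fs)
            x[i0 : i0 + len(tmpl)] += tmpl
            events.append(ev("c0", i0 / fs, i0 / fs + len(tmpl) / fs))
        rec = sk.Recording(x[None, :], fs, ["c0"])
        lags, avg_sp, _ = sk.time_shifted_average(rec, events, seed=0)
        np.testing.assert_allclose(avg_sp, tmpl, atol=1e-9)
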