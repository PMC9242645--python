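"""Rotating-wave direction indices on the 10-20 montage.

Simulates noise-free rotating-wave spindles (polar wavenumber +1 and -1),
estimates instantaneous phases from the analytic signal of the 9-18 Hz band,
and prints the aligned / anti-aligned direction indices.
"""
import numpy as np

import spindlekit as sk

names, theta = sk.montage_polar_angles("ten_twenty")
print(f"{len(names)} electrodes; polar angles from the anterior sagittal midline")

rng = np.random.default_rng(4)
for gamma in (+1, -1):
    aligned, anti = [], []
    for _ in range(100):
        cfg = sk.WaveConfig(
            A=1.0, omega=2 * np.pi * rng.uniform(11, 15), gamma=gamma,
            sigma=0.0, theta_n=theta, n_samples=1000, fs=1000.0,
        )
        rec = sk.rotating_wave_recording(cfg, seed=rng)
        rr = sk.rotation_indices(rec, 0.0, rec.duration)
        aligned.append(rr.mean_aligned)
        anti.append(rr.mean_anti)
    print(f"gamma={gamma:+d}: aligned index {np.mean(aligned):.3f}, "
          f"anti-aligned index {np.mean(anti):.3f}")
print("A value near 1 means the phase gradient matches that rotation sense;")
print("the opposite direction stays near the montage's no-synchrony floor")
print("(|mean exp(2i*theta)| ~ 0.13 for the classic 19-electrode cap).")
print("Reversing the wave swaps the two indices.")
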