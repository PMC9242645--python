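# Methods

This note records the models, parameter choices and numerical conventions
behind `spindlekit`, and what the synthetic validation does and does not
establish about real recordings.

## Time and data conventions

Times are seconds from recording start; intervals are half-open
`[t_start, t_end)`; sample `k` covers `[k/fs, (k+1)/fs)`. All detectors
score 500 ms windows on a 100 ms grid. Units are never rescaled on read:
the SNR detector is a power ratio, AT calibrates its threshold per
recording, and the CNN z-scores each window, so every detector is either
scale-invariant or self-calibrating.

Recordings are exchanged as HDF5 (`/data` channels×samples, `/fs`,
`/channel_ids`, optional `/region_labels`, `/polar_angle`), CSV (a `time`
column plus one column per channel) or 16-bit EDF. The EDF writer emits
one-second data records when the sampling rate divides the length evenly
and a single record otherwise; round trips are exact up to the format's
16-bit quantisation, and the test suite cross-checks the writer against an
independent EDF reader.

## Preprocessing

All filters are zero-phase (forward–backward), because the rotating-wave
analysis consumes instantaneous phases and cannot tolerate group delay.
Line noise is removed with narrow IIR notches (Q = 35) at the fundamental
and harmonics below min(fs/2, 100 Hz); the bandpass is a 4th-order
Butterworth applied forward–backward (≥ 20 dB one octave outside the band).
Common average referencing is available but off by default, since which
recording types warrant it is dataset-specific. The standard conditioning
chain is notch → 1–100 Hz bandpass (upper edge clipped to 0.475·fs so the
same call works at low sampling rates) → optional CAR.

## SNR detector

`SNR(w) = 10·log10(P_band/P_rest)` from a Hann-tapered periodogram of each
500 ms window; `P_band` integrates 9–18 Hz bins, `P_rest` integrates
1–100 Hz bins with the band excluded. A single taper is adequate at this
window length; the 100 ms stride matches the CNN grid so the two detectors
share window positions. Thresholds are per channel — the SNR distribution
is channel-specific, which is the point of the electrode-adaptive design —
at the 99th percentile with an optional 0 dB floor (on by default for
simulation work; 0 dB is parity between in-band and out-of-band power).
Supra-threshold windows whose spans overlap merge into one event
(time-overlap merging is required because 500 ms windows on a 100 ms grid
overlap even across a one-window gap); events outside 0.5–3 s are
discarded. For white noise the measure has a closed form,
`10·log10(9/90) ≈ −10 dB`, which anchors the unit tests.

Note one subtlety the tests respect: raising the threshold always shrinks
the *set* of supra-threshold windows, but the event *count* can transiently
rise when a long run splits; count-monotonicity is only asserted on smooth
surrogate traces.

## Training-set bootstrap

Spindle windows are 500 ms segments inside SNR events: the window at the
event's peak SNR first, then non-overlapping neighbours inside the event.
Non-spindle windows are drawn uniformly from start times with zero overlap
with any SNR event, at most twice the spindle count, targeting ≈1500
windows total. Everything is deterministic under the seed. Fewer than 50
SNR events triggers a warning (underpowered training), zero is an error.

## CNN

Architecture: five conv blocks (32/64/128/192/256 filters, max-pool 2,
ReLU), then fully connected 128/64/32/2 with ReLU and a softmax head.
Kernel spans are specified in milliseconds (90/45/22/11/6 ms defaults) and
converted via fs — this derivation of every sample-domain size from fs is
the entire per-modality tailoring rule. Same-padding stride-1 convolutions
preserve length; pooling is floor-mode, and the spec validator raises if a
pooling chain would collapse the map to zero length. Inputs are z-scored
per window, which gives the detector its approximate amplitude invariance.

Training: Adam (lr 1e-3), batch 64, up to 30 epochs with early stopping
(patience 6) on a stratified 10% held-out split, cross-entropy against the
SNR labels. The engine is plain numpy; single-thread CPU training is
bit-reproducible under a fixed seed, and every backward pass is checked
against numerical gradients in the tests. The end-to-end experiments use 8
epochs, which this problem size reaches convergence well within (held-out
loss plateaus near zero after 3–4 epochs).

Decision threshold on the softmax probability is 0.5. Positive windows
merge when they overlap or lie within 100 ms (boundary inclusive); the
merge code is shared with the AT detector, so identical positive-window
sets always give identical events.

Interpretation tools: per-conv-layer activation maps; saliency as the
gradient magnitude of the spindle logit with respect to the (z-scored)
input, with an optional gradient-times-input form. The bare gradient is the
textbook definition but, on our trained models, does not localise on the
oscillatory part of a mixed window (it is largest where perturbations could
most change the evidence, often the noise half); gradient-times-input does
localise on the spindle and on the larger-amplitude of two spindles, and is
the form used in the interpretation tests. Hyperparameter sensitivity
trains one model per grid point (learning rate, epochs, pooling within
±10–50%) and reports Cronbach's alpha across the models' window-probability
vectors, `α = k/(k−1)·(1 − Σσ²ᵢ/σ²_total)`.

## Amplitude-threshold baseline

11–15 Hz zero-phase bandpass, envelope as |analytic signal|; a window is
positive only if the envelope stays above threshold throughout — the
minimum-duration language of AT detectors implies the whole window must
clear the cutoff, implemented as min-over-window ≥ threshold. Events longer
than 3 s are discarded. Thresholds: rate-calibrated (per-electrode
bisection, 40 iterations over [0, max envelope], to 2 events/min ± 10%,
averaged across electrodes; silent or uncalibratable channels are excluded
with a warning) or a 3 SD multiple of the envelope (first/last 250 ms
excluded against Hilbert edge effects). In either mode the threshold is
*predetermined*: estimated once on a reference recording and reused. That
is both standard practice and the mechanism of AT's fragility — a 3 SD
threshold re-estimated on a rescaled recording would be exactly
scale-invariant, so the amplitude-halving control holds the baseline
threshold fixed, which is what the control is about.

## Surrogate generator

The generator defines the study conditions; its defaults are frozen.
Spindles are the real part of `A·e^{i(ωt+θ0)}` times an envelope — Hann
("waxing/waning", the default) or flat (used by the amplitude-control
experiment) — with f ~ U(11,15) Hz, θ0 ~ U(0,2π), durations U(0.5,3) s.
Event counts per channel are Poisson(rate·duration) conditioned on
non-overlapping placement (50 ms guard, 10⁴ bounded retries). Noise kinds:
white, pink (1/f) and Brownian (1/f²), generated by exact spectral shaping
of white noise and normalised to the requested RMS; "1/f noise" and "pink
noise" are one kind. Theta distractors draw 4–8 Hz and 400–1000 ms.
Artifacts are phase-randomised instances of unit-RMS parametric templates:
a damped chirp (24→6 Hz, 1.2 s), a smoothed step with slow decay (1 s) and
a sustained broadband burst (1 s, EMG/movement-like, internally seeded).
The burst exists because artifact libraries harvested from real recordings
consist of transients that amplitude thresholding mistakes for spindles;
only a sustained broadband transient can hold the narrow-band envelope
above threshold for a full 500 ms window while keeping a low band-power
*ratio* (invisible to the SNR measure). Phase randomisation preserves the
amplitude spectrum exactly (conjugate-symmetric random phases, real
output).

Standard conditions used by the experiments, chosen to give the clear
spindle-band PSD peak the controls assume and frozen before any acceptance
run: fs 200 Hz for surrogate work (all window sizes derive from fs);
amplitude-control: 1 channel × 60 min, 3 flat spindles/min, A = 1, white
RMS 0.25 + Brownian RMS 0.15 (in-window spindle SNR ≈ +8 dB at baseline,
still above the 0 dB floor when amplitude is halved or noise doubled);
noise-spectrum study: 10 channels × 10 min, 2 Hann spindles/min, noise RMS
0.25; artifact sweep: 5 channels × 8 min, artifact RMS 1.2, rates 0–10/min.

Rotating waves: channel n carries `Re[A·e^{i(ωt−γθₙ)}] + σ·η(t)`, γ the
polar wavenumber. Electrode polar angles are the azimuth about the vertex
axis measured from the anterior sagittal midline (the polar convention of
the standard top-view 10–20 layout): θ=0 anterior midline, +π/2
right-lateral, ±π posterior. Named montages are the classic 19-electrode
10–20 set and a 64-channel 10-10 extension, with positions from the
standard montage tables; a 10×10 grid montage sweeps the circle uniformly
(its doubled-angle sum is exactly zero).

## Rotation indices

Phases xₙ(t) come from the analytic signal of the 9–18 Hz zero-phase
bandpassed channels over the event interval, with 100 ms trimmed at each
end (Hilbert edge effects) when the interval allows. The printed form of
the index is complex with an ambiguous normaliser; it is implemented as the
magnitude of the complex mean with 1/N normalisation — the single most
consequential interpretation in the codebase, chosen because the reported
values live in [0,1] — with real-part and modulus-of-time-mean variants
behind a flag. The scalar summary is the time mean of the per-sample
magnitude.

Two exact facts shape expectations here. For a noise-free wave with γ=+1,
the aligned sum collapses to `|e^{iωt}| = 1` *identically*, independent of
the montage; and the anti index equals the montage constant
`|mean e^{2iθ}|` (0.128 for the classic 19-electrode cap under the
convention above — essentially the 1/√N no-synchrony floor). The
1000-simulation experiment therefore reports an aligned index of ≈1.000
(exact recovery, the behaviour the simulation is designed to certify) and
an anti index of ≈0.129, swapping under wave reversal.

## Scoring and spatial statistics

A detected event matches a true spindle when their intervals overlap by at
least 50% of the shorter; matching is one-to-one and optimal (maximum
cardinality, then maximum overlap, via linear assignment), verified against
exhaustive enumeration in the tests. Extent classes count channels with an
overlapping event per detection-grid window: local 1–2, regional 3–10,
multi-area >10; an event that starts local and spreads contributes windows
to both regimes. Array-level events are connected components of the
temporal-overlap relation across channels (sweep algorithm, transitive);
the multi-electrode rate counts components per minute and can never exceed
the single-electrode rate. Region participation is the percentage of
recorded region groups represented in an array-level event.

Validation analyses: Welch PSD contrast averages Hann periodograms over
non-overlapping 500 ms windows tiling events versus count-matched random
windows with zero event overlap (seeded). Time-shifted averaging aligns
each event at its largest positive sample and averages ±0.5 s segments of
the 1 Hz-highpassed signal; the matched control applies the identical
procedure to random non-event windows, so its central alignment peak decays
with the signal's autocorrelation and shows no 11–15 Hz structure.

## What the synthetic validation shows — and does not

The surrogates share the statistical skeleton of sleep recordings (band-
limited bursts in colored noise, distractors, artifacts) but not their
physiology: no slow-oscillation coupling, no spindle morphology beyond a
Hann envelope, no biophysical (thalamocortical) generative model, iid
event placement, and stationary noise. Passing the end-to-end bar
(event-level F1 ≥ 0.8 per noise spectrum) certifies the machinery — label
bootstrap, training, inference, merging, scoring — under known ground
truth; it does not certify detection quality on any particular real
dataset, where expert-scored baselines remain the arbiter. Likewise the
rotating-wave experiment certifies the direction metric, not the
prevalence of rotating waves in real sleep. Problem sizes in the tests
(10 min × 10 channels at 200 Hz, 8 training epochs, 150–1000 wave
simulations) are the package's reference conditions; results are stable
across seeds at these sizes.

## Known limitations

No BrainVision/EEGLAB/Neuralynx readers; no re-referencing beyond CAR; no
resampling beyond what callers do themselves; no multichannel (2-D)
convolution or cross-subject transfer; the AT baseline implements only the
rate-calibrated and SD-multiple variants it is compared against; no
statistical machinery for human cohort comparisons.
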