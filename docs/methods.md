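# Methods

`tailored_tacs` implements an EEG-informed pipeline for individualizing
transcranial alternating current stimulation (tACS): resting-state EEG is
reduced to per-electrode relative band power, compared against a healthy
normative cohort as a z statistical map, and the site and band of the largest
power excess determine the stimulation frequency and montage. Around that
core the package provides the crossover outcome statistics (paired Wilcoxon
signed-rank contrasts) and a Monte-Carlo power analysis of the signed-rank
test on discrete score differences, plus a synthetic-data generator that
stands in for unavailable patient recordings.

## Spectral analysis

A recording is a channel × sample matrix in µV with a 10/10 montage. The
processing chain is the standard clinical quantitative-EEG sequence:

1. **Resample to 500 Hz** with a polyphase FIR anti-alias resampler
   (`scipy.signal.resample_poly`); input below 500 Hz is rejected.
2. **Band-pass 1–30 Hz, zero-phase.** A 4th-order Butterworth high-pass at
   1 Hz and an 8th-order Butterworth low-pass at 30 Hz, each applied
   forward–backward (`sosfiltfilt`) so the output carries no group delay.
   The two-stage design keeps the section Q low; the low-pass order is
   chosen so that broadband energy just outside the band is suppressed by
   more than two orders of magnitude in PSD (a single 4th-order band-pass
   leaves ~5 % PSD at 35 Hz relative to mid-band, which would leak into the
   beta band total). Up to 1 s per edge is discarded after filtering — the
   1 Hz high-pass rings for about a second, and zero-phase filtering places
   that settle-in inside the data — but a short recording is never trimmed
   below one epoch.
3. **Common average reference**: each sample's across-channel mean is
   subtracted; idempotent by construction.
4. **Epoching**: non-overlapping 2-s epochs (1000 samples at 500 Hz); the
   trailing remainder is discarded.
5. **PSD**: mean over epochs of Hamming-windowed one-sided periodograms
   (Welch with zero overlap), window-power normalized so the PSD integral
   equals the mean-square amplitude; grid spacing 0.5 Hz, units µV²/Hz.
6. **Relative band power**: band power is the sum of PSD bins whose center
   lies in the band's closed interval — delta [1, 4], theta [4.5, 7.5],
   alpha1 [8, 10], alpha2 [10.5, 12.5], beta [13, 30] Hz — divided by total
   power over 1–30 Hz, × 100. The closed-interval convention resolves the
   half-bin gaps between printed band edges: at 0.5 Hz spacing the five
   bands exactly partition the 59 bins from 1.0 to 30.0 Hz (7/7/5/5/35
   bins), and every channel's five percentages sum to 100.

PSD is averaged across epochs *before* the single division by total power;
averaging per-epoch relative powers instead was considered and rejected so
that the estimate stays a ratio of consistent power estimates (for
stationary signals the two agree within tolerance anyway).

Manual artifact handling (e.g. visual selection of independent components)
is out of scope; `preprocess` accepts an `artifact_hook` callable through
which externally cleaned data can be passed.

## Normative z-map and stimulation planning

The normative model is the cell-wise sample mean and SD (n − 1 denominator)
of relative power across control subjects — between-subject SD, not
within-subject epoch SD, because the comparison is one participant versus a
cohort. A subject's z-map is `z = (subject − mean) / SD` per electrode ×
band, flagged significant two-sided at p < 0.05 (|z| ≥ 1.959964). At least
two controls are required and a zero-SD cell is an error naming the cell.

The **prevailing rhythm** is the cell with the maximum significant positive
z; ties break deterministically by band order (delta → beta) then montage
order. If no cell shows a significant positive excess the result is an
explicit no-target outcome (`None`), not an exception.

The decision rule opposes the excess: a slow-band excess (delta, theta,
alpha1) maps to 30 Hz beta-tACS, a fast-band excess (alpha2, beta) to 4 Hz
theta-tACS. The anode sits over the peak electrode; the cathode over the
ipsilateral mastoid (odd electrode numbers → M1, even → M2). Midline anodes
have no ipsilateral mastoid; a fixed adjacent-midline map is used
(Cz → Fz, Pz → Cz, …) and a `cathode_override` field accepts the montages a
clinician may prefer (published assignments include both Cz–Fz and Cz–Pz
pairs). Multi-site anode pairs are outside the automatic rule; the planner
emits the single peak electrode.

Amplitudes stay in 1–2 mA. tACS waveforms are fixed-frequency sinusoids;
the active sham (random noise stimulation, RNS) is a phase-continuous chirp
whose instantaneous frequency (Uniform 0–100 Hz) and amplitude (Uniform
1–2 mA) are redrawn every 50 ms, which spreads energy across the whole
0–100 Hz range with no dominant line while keeping every sample below 2 mA.

## Crossover statistics

Outcomes are long-format rows (subject, sequence, timepoint, condition,
measure, value) over the crossover schedule: baseline T0, post-cycle T1/T1′,
post-wash-out T2/T2′, with T1/T2 belonging to the first-arm condition.
Default contrasts per measure: T0 vs T1, T0 vs T2 and T1 vs T2 within each
condition, plus tACS vs RNS at T1 and at T2. Data from both sequence orders
are pooled by condition; period effects are not modeled. Pairing is by
subject on complete cases; contrasts with fewer than two complete pairs are
skipped with a logged warning. No multiple-comparison correction is applied
anywhere — the analysis is exploratory by design.

The signed-rank test drops zero differences (Wilcoxon's original rule),
then:

- **tie-free and n ≤ 25**: exact two-sided p from the full null
  distribution of W⁺ computed by rank convolution,
  `p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))`;
- **otherwise**: normal approximation with the standard tie correction
  (average ranks; variance reduced by Σ(t³ − t)/48), no continuity
  correction.

All-zero differences give a degenerate result with p = 1 and a flag. The
location estimate is the Hodges–Lehmann median of all Walsh averages
(d_i + d_j)/2, i ≤ j; the 95 % CI endpoints are the k-th smallest/largest
Walsh averages with k from the same exact null distribution (normal
approximation beyond n = 25). When the attainable confidence level falls
below the request (tiny n) the CI widens to the full Walsh range.

## Power simulation

Power of the signed-rank test on n i.i.d. discrete differences is estimated
by simulation (default 10,000 replicates; binomial Monte-Carlo SE reported)
and, for |support|^n ≤ 10⁷, computed exactly by enumerating outcome
multisets weighted by multinomial probabilities. Both routes call the same
test implementation used for the trial contrasts, so the reported power is
that of the tie-corrected test actually applied (integer supports guarantee
ties). The discrete-distribution median uses the midpoint convention — a
CDF that hits exactly 0.5 at a support point yields the midpoint of that
point and the next, which is how a half-integer median arises on an integer
score scale (uniform on {1, 2} → 1.5).

The study whose design this package mirrors did not publish its empirically
observed VAS-difference probabilities; the shipped example distribution on
−1…6 (median 1.5) is therefore explicitly illustrative, and the power the
package reports for it is not comparable to any published power figure.

## Synthetic data generator

The generator emulates five-minute, 32-channel, open-eyes resting EEG
acquired at 5 kHz (defaults: `fs=5000`, `duration_s=300`, the standard
32-electrode 10/10 cap). Signals are synthesized in the frequency domain:
each channel's rFFT coefficients are complex Gaussian with expected
amplitude A(f) = `noise_amplitude`·f^(−γ/2) plus a flat component of
amplitude `band_gain` inside each band interval (γ = 1 by default). This
gives exact control of the expected spectrum, which is what the spectral
oracles need. Band oscillations are band-limited noise rather than pure
sinusoids so that normative SDs never degenerate to zero.

Between-subject variability multiplies each band's amplitude by a
mean-preserving log-normal factor with coefficient of variation
`band_gain_cv = 0.2` — positive by construction and in the range of
between-subject band-power spread reported for healthy resting EEG. A
planted anomaly multiplies the *total* spectral amplitude inside the target
band at the target electrodes by `gain_factor`, so band power scales by
exactly `gain_factor²` before renormalization. No volume conduction is
modeled by default (the maps of interest are per-electrode); an optional
neighbor-blend `smoothing` weight exists. No blink/ECG/EMG artifacts are
synthesized.

Synthetic outcome tables draw subject baselines (Gaussian between-subject
SD 1), add per-(condition, timepoint) location shifts and Gaussian noise
(SD 1), clamp to the measure's score range, and delete post-baseline
observations with probability `missing_rate`. Every generator is a pure
function of (spec, seed).

**What passing tests show — and don't.** The planted-anomaly recovery and
null-calibration results demonstrate that the pipeline's statistics behave
as designed under a stationary, artifact-free, spatially uncorrelated signal
model. Real resting EEG is nonstationary, spatially correlated through
volume conduction, and artifact-laden; recovery rates measured here are an
upper bound on what identical settings would achieve on recorded data.

## Problem sizes and numerical conventions

Tests and the acceptance script run the generator at 500 Hz / 20-s
recordings (9 usable epochs after edge trimming) — the full 5 kHz × 300 s
default is exercised for correctness but not for replicate studies, whose
sizes are: 100 (tests) or 50 (script) recovery replicates at anomaly gain 3
(the worked z-map example's value; at the boundary gain of exactly 2 the
recovery rate sits at about 93–96 %, limited by log-normal tail events in
the 160 null cells rather than by estimation noise), 2000 zero-effect
contrasts for null calibration, and 10,000 power replicates. Determinism:
all randomness flows from `numpy.random.default_rng` / `SeedSequence`
spawning, so every artifact is reproducible bitwise from a single seed.

Known limitations: no EDF writer is provided (recordings are written as CSV
channel matrices with a YAML side-car; EDF files are read via mne); no
mixed-effects or period-effect crossover modeling; no electric-field or
head-conductivity modeling; clinical instruments enter as numeric scores
only.
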