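# Methods

This note records the models, conventions and numerical choices behind
`ictalab`, including the places where the underlying analysis definitions
leave room for interpretation and what this package chose.

## Signal model and units

All signals are microvolts, channels × samples, at 1000 or 2000 Hz (the
two acquisition rates the pipeline supports). Times are seconds from
recording start; event intervals are half-open `[onset, offset)`, so
duration = offset − onset and adjacent events share no samples. EDF files
are written as plain 16-bit EDF with a symmetric physical range covering
the data (quantization step = range/65535, documented in the writer);
float32 binary + text sidecar is provided as a lossless fixture format.

## Seizure detection

Definition implemented: a seizure is an interval whose sliding-RMS
envelope is **at least** 3 SD above the baseline RMS amplitude
(inclusive ≥), lasting **strictly more than** 5 s, with dominant
frequency **strictly above** 3 Hz.

Choices the definition does not pin down:

- *Envelope*: RMS in 1 s windows stepped by 0.5 s. One-second windows
  resolve the > 5 s minimum duration comfortably while averaging enough
  samples for a stable estimate.
- *What "3 SD above baseline RMS" references*: the mean and SD of the
  sliding-RMS series itself over the baseline interval (not the SD of
  raw samples). The threshold is then `rms_mean + k·rms_sd`, i.e. k is
  measured in units of the envelope's own variability. This is an
  interpretation; it makes the threshold scale-free and ties directly to
  the amplitude calibration of the synthetic generator (below).
- *Merging*: supra-threshold runs separated by < 2 s are merged before
  the duration test, so envelope dips inside one discharge do not split
  it. Configurable.
- *Edge refinement*: the coarse 1 s windows smear event boundaries by up
  to one window, which would systematically inflate measured durations
  (a true 4.9 s event would read ≈ 5.5 s and wrongly pass the > 5 s
  rule). Each merged candidate is therefore refined with a second RMS
  pass at window/4 (step window/20) over the candidate ± one coarse
  window, keeping the contiguous supra-threshold run around the envelope
  peak (sub-threshold flickers of ≤ 3 fine steps are bridged). Short
  windows fluctuate more, so isolated noise crossings near the event are
  deliberately not allowed to stretch it. Onset localization is ~0.15 s
  on 8-SD events.
- *Rhythmicity*: the peak of a Welch PSD (1 s sub-windows, 50% overlap,
  evaluated from 1 Hz to Nyquist) of the raw (notched) segment — the
  oscillation itself, not its envelope, must exceed 3 Hz.
- *Best channel*: the channel with the most detected seizures is used
  for power analysis; ties resolve to the lowest channel index.
- *Slice recordings*: interictal-like events are detected with the same
  machinery, lowering `min_duration` via `DetectorParams`; recovery time
  after washout is the offset of the last event minus the washout time,
  right-censored at the 60-min recording stop.

## Morlet wavelet time-frequency analysis

Wavelets `w(t) = exp(i2πft)·exp(−t²/(2σ²))` with `σ = n/(2πf)` exactly;
frequencies linearly spaced (default 1–200 Hz in 200 steps) with the
cycle count n interpolated linearly 1 → 30 across the axis. One shared
kernel length (odd, ≥ 6·σ_max·fs samples) is used for all frequencies.

Convolution is FFT-domain multiplication of signal and kernel spectra;
an explicit test asserts equivalence with direct time-domain convolution
to better than 1e-6 relative error. The signal is reflection-padded by
3·σ_max·fs samples (trimmed after the transform) so edges carry no
fabricated power; onset-aligned trials whose −5 s pre-window would leave
the recording are dropped, not zero-padded.

*Gain convention.* Each kernel's spectrum is max-normalized and the
kernel scaled by 2 (analytic-signal convention): a real tone of
amplitude A at a bin frequency yields coefficient magnitude ≈ A. Without
the factor 2 a unit tone would read 0.5, since the complex kernel passes
only the positive-frequency half of a real signal.

*Power.* Default power is the coefficient magnitude `|W|` — the literal
"magnitude" convention — with `|W|²` available and recorded in the
output metadata. Consequence of magnitude mode: doubling signal
amplitude adds +3.01 dB (not +6.02).

*dB normalization.* `10·log₁₀(P/P_baseline)` per frequency, where
`P_baseline` is the time-averaged power over a designated baseline
interval on the same channel (default: the last 20 min of the baseline
period, mirroring a wakefulness-subset convention; configurable). The
reference must be strictly positive; zero-signal baselines are rejected
rather than propagated as −∞. Note that time-averaging power *before*
the log is the self-consistent identity (a stationary interval
normalizes to 0 dB); averaging instantaneous dB values over time carries
a negative Jensen offset inherent to log transforms, which applies
equally to all groups being compared.

*Bands*: delta 1–3, theta 4–8, alpha 9–13, beta 14–30, gamma 31–80,
HFO 81–200 Hz (inclusive bin selection); the intrahippocampal table
(global 0–500, HFO 80–500 Hz) requires 2 kHz recordings — at 1 kHz,
500 Hz is the Nyquist frequency and the axis cannot reach it.

*Aggregation*: per-seizure (each seizure one trial; depth-LFP
convention) or per-animal (trials averaged within animal, and across
channels when present; skull-array convention). Seizures within an
animal are treated as independent trials in per-seizure mode — a known
simplification, flagged here rather than replaced by mixed models.

## Topographic maps

Per-channel dB values are interpolated over planar electrode coordinates
with thin-plate-spline radial basis functions: exact at electrode sites,
exact for planar fields, masked outside the convex hull of the array (no
extrapolation), clipped to the range of the channel values. Real layout
coordinates load from TSV; a 5×6 grid generator stands in when the
implant schematic is unavailable.

## Statistics

- Kaplan–Meier product-limit estimates (lifelines) with right-censoring.
- Gehan–Breslow–Wilcoxon: implemented from Gehan scores
  `U_i = #(definitely outlived) − #(definitely outlived by)`; statistic
  `W = Σ_{i∈A} U_i` with permutation variance
  `n_A n_B ΣU² / (N(N−1))`, chi-square(1) asymptotic p, and an optional
  vectorized permutation p. Cross-checked against the wilcoxon-weighted
  logrank test (a variance-estimator variant of the same test family).
- Death-rate comparison: two proportions with two-sided Fisher exact p.
- Band comparisons: unpaired Student t by default (Welch optional);
  one-way ANOVA + Tukey HSD; two-way ANOVA (type-II) for
  treatment × hemisphere designs. No multiple-testing correction across
  bands (per-band tests are reported raw, and the output says so).
- Recovery times: censored observations enter group means at the 60-min
  cap exactly — an all-censored group summarizes to 60.00 ± 0 — with the
  censored fraction reported alongside so the convention is never
  silent. A KM-based treatment of the same data is available for users
  who prefer it.
- Significance level: α = 0.05 by default; a stricter 0.005 can be
  passed wherever α is a parameter.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-genotype acute
seizure-induction experiment, not its biophysics:

- **Background**: 1/f noise (default exponent 1) synthesized in the
  frequency domain with uniform random phases — exact slope control —
  scaled to 50 µV RMS per channel, plus a 50 Hz line sinusoid (5 µV
  default). Optional per-band power multipliers implement group-level
  background spectrum offsets (e.g. ×4 power in theta = +6 dB).
- **Ictal events**: fundamental + 2 harmonics (1 : 0.3 : 0.15) under a
  Tukey envelope; the taper is 10% of event duration per side, capped at
  0.5 s so that the supra-threshold crossing of long events stays within
  the detector's 1 s onset-localization contract. The envelope starts
  and ends at zero (no splice discontinuity); samples outside scheduled
  events are bit-identical to the background.
- **Amplitude calibration**: event amplitudes are specified in multiples
  k of the baseline RMS-SD and converted per channel to an added-signal
  RMS s via `sqrt(rms_mean² + s²) = rms_mean + k·rms_sd`, so an injected
  k-SD event sits at exactly k SD on the detector's own scale.
- **Design**: 1 h baseline then 3 h post-injection observation by
  default; per-animal event counts Poisson with the group rate; first
  event at a truncated-normal latency; durations truncated normal
  (≥ 6 s, inside the detectable regime); fundamentals uniform in
  5–12 Hz. Default group parameters encode a susceptible-vs-wild-type
  contrast (rates 0.28 vs 7.3 events/h; durations 10 vs 21.6 s mean;
  latencies 54 vs 27 min) matching the effect directions of the
  experimental designs this pipeline targets. Ground-truth events closer
  than 1 s merge, consistent with detector post-processing.
- **Survival cohorts**: discrete 30-min dosing steps with per-group
  per-step hazard; censoring at max dose.

Everything is deterministic under a fixed seed (`numpy.SeedSequence`
spawning per animal).

What the generator does **not** model — and hence what passing tests do
not certify about real data: spike-wave morphology, postictal
suppression, movement and electrode artifacts, non-stationary background
(sleep/wake transitions), inter-channel propagation delays, and
mortality. Detection performance on real recordings depends on exactly
those nuisances; the synthetic results validate the machinery, not
field performance.

## Validation problem sizes

The seeded experiments in `ictalab.validation` (run by
`scripts/acceptance.py` and the acceptance tests) use desk-scale versions
of the designs: detection fidelity on six 20-min single-channel
recordings packed with ≥ 100 events of 8–30 s at 5–12 Hz and 8 SD;
false-positive control on twenty seizure-free hours; effect recovery on
twenty cohorts of 10 animals/group with 10-min baselines and 30-min
post-injection windows, a 10× rate ratio and +6 dB theta offset; GBW
agreement on 12 animals/group over ten dosing steps with hazards
0.2 vs 0.6 per step and a 10⁴-permutation reference. These sizes were
chosen so the whole validation battery completes in minutes on one CPU
while keeping Monte-Carlo error well inside the margins being asserted.

## Known limitations

- The detector's duration estimate is conservative near the 5 s
  boundary by design (edge refinement anchors on the contiguous
  supra-threshold run); events hovering exactly at threshold may be
  truncated at internal dips longer than ~0.15 s.
- Magnitude-vs-squared power is a genuine convention fork; both are
  implemented and flagged in outputs, with magnitude as the default.
- Wakefulness scoring is not implemented; baseline intervals are
  supplied explicitly.
- EDF support is plain EDF (no EDF+ annotations embedded in the data
  stream); annotations travel in separate TSV event tables.
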