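# ictalab

Offline analysis of rodent EEG/LFP seizure recordings: automatic seizure
detection by baseline-RMS thresholding, complex Morlet wavelet
time-frequency quantification of seizure power in canonical frequency
bands (dB relative to baseline), topographic multichannel power maps,
seizure-threshold survival analysis, and censoring-aware recovery-time
summaries for slice washout experiments — together with a seeded
synthetic-cohort generator with known ground truth, so every stage of the
pipeline can be validated end to end without animal data.

It is aimed at electrophysiology groups running chemoconvulsant (e.g.
kainate) seizure-induction experiments in two-genotype designs who want a
tested, reproducible replacement for one-off analysis scripts.

## The methods in brief

**Seizure detection.** A seizure is a rhythmic (> 3 Hz) oscillation
lasting > 5 s whose sliding-RMS envelope is at least 3 standard deviations
above the baseline RMS amplitude. The detector computes a 1 s / 0.5 s
sliding RMS, thresholds it at `mean + 3·SD` of the baseline envelope,
merges supra-threshold runs separated by < 2 s, sharpens event edges with
a short-window refinement pass, and keeps events that pass the strict
duration and rhythmicity (Welch peak frequency) rules. Every emitted
event is re-verifiable from the raw signal.

**Time-frequency quantification.** Complex Morlet wavelets
`w(t) = exp(i2πft)·exp(−t²/2σ²)` with `σ = n/(2πf)` and the cycle count
`n` ramping linearly 1 → 30 across 200 frequency steps (1 → 200 Hz by
default). Convolution is done in the frequency domain; power is the
coefficient magnitude `|W|`; trials are aligned to seizure onset
(−5 … 40 s for depth LFP, −5 … 30 s for the 30-channel skull array) and
expressed as `10·log₁₀(P/P_baseline)` per frequency against a baseline
recording. Band summaries use delta (1–3 Hz), theta (4–8), alpha (9–13),
beta (14–30), gamma (31–80) and HFO (81–200), or global 0–500 / HFO
80–500 Hz for 2 kHz intrahippocampal recordings.

**Statistics.** Kaplan–Meier curves and the Gehan–Breslow–Wilcoxon test
for repeated-injection seizure-threshold designs (with a permutation
option), Fisher-exact death-rate comparison, per-band unpaired t-tests,
one-/two-way ANOVA with Tukey HSD, and recovery-time summaries in which
observations censored at the 60-min recording stop enter at the cap.

## Worked example

```bash
ictalab demo --out demo_results --seed 0
```

generates a 2×3-animal synthetic cohort (5-min baseline, 10-min
post-injection window, the "KO-like" group seizing more often), runs the
full pipeline and prints, among other tables:

```
## Group comparisons
       metric       test  mean_WT-like  mean_KO-like  statistic        p  ...
        theta unpaired_t      0.730279      3.465223  -3.440127 0.003363
        alpha unpaired_t      1.869948      5.367815  -3.093140 0.006979
seizure_count unpaired_t      1.333333      5.000000  -2.345208 0.078928

## Detection vs ground truth
 tp  fp  fn  precision  recall  median_abs_onset_error_s
 38   0   0        1.0     1.0                   0.17746
F1 = 1.000
```

Reading: the detector recovered all 38 injected events with no false
positives and ~0.2 s onset accuracy; ictal power in the theta and alpha
bands (where the synthetic ictal oscillations live, 5–12 Hz) is
significantly higher in the KO-like group, while the per-animal seizure
count difference at n = 3/group does not reach significance — small-n
behavior the cohort generator makes easy to explore.

The same stages are available as library functions
(`ictalab.detect.detect_seizures`, `ictalab.tfr.tfr_stack`, …) and as the
subcommands `synth`, `detect`, `tfr`, `run`, `report`.

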