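"""Synthetic ictal EEG with known ground truth.

The generator emulates the statistical structure of an acute chemoconvulsant
experiment: a baseline period followed by a post-injection observation
window in which rhythmic ictal events appear with group-dependent rate,
latency, duration and amplitude. Background activity is 1/f ("pink") noise
with optional band-limited power offsets per group, plus 50 Hz power-line
contamination. Ictal events are a fundamental oscillation with two weaker
harmonics under a tapered envelope; their amplitude is specified in
multiples of the baseline sliding-RMS standard deviation, the same scale
the detector thresholds on.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import sliding_rms
from .signal_io import Recording
from .tfr import BANDS

__all__ = [
    "SynthCohortConfig",
    "GroundTruth",
    "gen_background",
    "gen_ictal_segment",
    "inject_events",
    "gen_cohort",
    "gen_survival_cohort",
    "RAMP_MAX_S",
]

# envelope ramp: 10% of event duration per side, capped so that detected
# onsets stay within the 1 s localization contract for long events
RAMP_MAX_S = 0.5

TRUTH_MERGE_GAP_S = 1.0   # ground-truth events closer than this merge
MIN_EVENT_DURATION_S = 6.0


@dataclass
class SynthCohortConfig:
    """Cohort-level generation parameters; defaults mirror an acute
    two-genotype seizure-induction experiment (1 h baseline, 3 h
    post-injection, susceptible group with higher rate and longer events).

    Per-group pairs are ordered as ``group_labels``. ``seizure_rate`` is in
    events/hour; ``duration_dist``/``latency_dist`` are (mean, SD) in
    seconds, durations truncated at ``MIN_EVENT_DURATION_S``;
    ``ictal_amplitude_sd`` is in multiples of the baseline RMS-SD;
    ``band_gain`` maps band name -> power multiplier per group (2 doubles
    power, +3 dB).
    """

    n_animals_per_group: int = 9
    group_labels: tuple[str, str] = ("WT-like", "KO-like")
    fs: float = 1000.0
    n_channels: int = 2
    duration_baseline: float = 3600.0
    duration_post: float = 10800.0
    seizure_rate: tuple[float, float] = (0.28, 7.3)
    duration_dist: tuple[tuple[float, float], tuple[float, float]] = (
        (10.0, 3.0), (21.6, 7.0))
    latency_dist: tuple[tuple[float, float], tuple[float, float]] = (
        (3240.0, 2160.0), (1630.0, 970.0))
    ictal_freq_range: tuple[float, float] = (5.0, 12.0)
    ictal_amplitude_sd: tuple[float, float] = (8.0, 8.0)
    band_gain: tuple[dict, dict] = field(default_factory=lambda: ({}, {}))
    pink_exponent: float = 1.0
    line_amp: float = 5.0
    background_rms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValueError("need at least one animal per group")
        if self.fs not in (1000.0, 2000.0):
            raise ValueError("fs must be 1000 or 2000 Hz")
        if self.duration_baseline <= 0 or self.duration_post <= 0:
            raise ValueError("durations must be positive")
        if any(r < 0 for r in self.seizure_rate):
            raise ValueError("seizure rates must be non-negative")


@dataclass
class GroundTruth:
    """Injected events (one row per animal/channel/event) plus the
    parameters actually used and the envelope ramp length."""

    events: pd.DataFrame
    injected_params: dict
    ramp_s: float = RAMP_MAX_S


def _pink_spectrum_shape(freqs: np.ndarray, exponent: float,
                         band_gain: dict | None) -> np.ndarray:
    """Amplitude shaping per rFFT bin: f^(-exponent/2) with optional
    per-band amplitude boosts (sqrt of the power gain)."""
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2)
    shape[0] = 0.0  # no DC
    if band_gain:
        for band, gain in band_gain.items():
            low, high = BANDS[band] if isinstance(band, str) else band
            sel = (freqs >= low) & (freqs <= high)
            shape[sel] *= np.sqrt(gain)
    return shape


def gen_background(fs: float, duration: float, n_channels: int,
                   pink_exponent: float = 1.0, line_amp: float = 5.0,
                   seed: int | np.random.Generator = 0,
                   band_gain: dict | None = None,
                   target_rms: float = 50.0) -> Recording:
    """1/f background with 50 Hz line contamination, no ictal events.

    Synthesized in the frequency domain (amplitude ~ f^(-exponent/2),
    uniform random phases) for exact spectral-slope control, scaled to
    ``target_rms`` µV per channel, then the 50 Hz sinusoid of amplitude
    ``line_amp`` µV is added.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if pink_exponent < 0:
        raise ValueError("pink_exponent must be >= 0")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = _pink_spectrum_shape(freqs, pink_exponent, band_gain)
    samples = np.empty((n_channels, n))
    for c in range(n_channels):
        mag = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
        x = np.fft.irfft(mag * shape, n)
        rms = np.sqrt(np.mean(x * x))
        samples[c] = x * (target_rms / rms) if rms > 0 else x
    if line_amp > 0:
        t = np.arange(n) / fs
        samples += line_amp * np.sin(2 * np.pi * 50.0 * t)
    return Recording(samples, fs, [f"ch{i}" for i in range(n_channels)])


def _ramp_alpha(duration: float) -> float:
    """Tukey alpha for a 10%-per-side taper capped at RAMP_MAX_S."""
    return min(0.2, 2 * RAMP_MAX_S / duration)


def gen_ictal_segment(fs: float, duration: float, fundamental: float,
                      amplitude: float = 1.0,
                      phase: float = 0.0) -> np.ndarray:
    """One rhythmic ictal burst: fundamental plus two weaker harmonics
    (relative amplitudes 1 : 0.3 : 0.15) under a Tukey envelope.

    ``amplitude`` is the peak amplitude of the fundamental in µV. The
    envelope starts and ends at zero, so splicing into a background
    introduces no step discontinuity. Harmonics above Nyquist are omitted.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fundamental <= 0:
        raise ValueError("fundamental must be positive")
    if fundamental >= fs / 2:
        raise ValueError(
            f"fundamental {fundamental} Hz at or above Nyquist ({fs / 2} Hz)")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for mult, rel in ((1, 1.0), (2, 0.3), (3, 0.15)):
        f = mult * fundamental
        if f < fs / 2:
            x += rel * np.sin(2 * np.pi * f * t + phase * mult)
    env = sps.windows.tukey(n, alpha=_ramp_alpha(duration))
    return amplitude * x * env


def _amplitude_for_sd(rms_mean: float, rms_sd: float, k: float) -> float:
    """Added-signal RMS s such that the in-event window RMS sits k SD
    above the baseline mean: sqrt(mean^2 + s^2) = mean + k*sd."""
    return float(np.sqrt((rms_mean + k * rms_sd) ** 2 - rms_mean ** 2))


def inject_events(rec: Recording, schedule: list,
                  seed: int = 0) -> tuple[Recording, GroundTruth]:
    """Add scheduled ictal events to a background recording.

    ``schedule`` rows are ``(channel_id, onset_s, duration_s,
    fundamental_hz, amplitude_sd)`` with amplitude in multiples of the
    channel's baseline RMS-SD (computed here from the clean background
    with 1 s / 0.5 s sliding windows). Samples outside the scheduled
    intervals are unchanged. Ground truth lists the schedule with
    overlapping or near-adjacent (< 1 s gap) events on a channel merged.
    """
    out = rec.copy()
    rng = np.random.default_rng(seed)
    stats = {}
    for ci, cid in enumerate(rec.channel_ids):
        _, rms = sliding_rms(rec.samples[ci], rec.fs, 1.0, 0.5)
        stats[cid] = (float(rms.mean()), float(rms.std(ddof=1)))
    rows = []
    for cid, onset, dur, fund, amp_sd in schedule:
        if onset < 0 or onset + dur > rec.duration + 1e-9:
            raise ValueError(
                f"event {onset}..{onset + dur} s exceeds recording "
                f"(0..{rec.duration:.1f} s)")
        mean, sd = stats[cid]
        target_rms = _amplitude_for_sd(mean, sd, amp_sd)
        seg = gen_ictal_segment(rec.fs, dur, fund,
                                phase=rng.uniform(0, 2 * np.pi))
        seg_rms = np.sqrt(np.mean(seg * seg))
        seg *= target_rms / seg_rms
        i0 = int(round(onset * rec.fs))
        out.samples[rec.channel_index(cid), i0: i0 + seg.size] += seg
        rows.append((cid, float(onset), float(onset + dur),
                     float(fund), float(amp_sd)))
    truth = _merge_truth(rows)
    return out, GroundTruth(truth, {"schedule": list(schedule)})


def _merge_truth(rows: list, animal_id: str = "a0") -> pd.DataFrame:
    """Per-channel merge of overlapping / near-adjacent truth events."""
    cols = ["animal_id", "channel_id", "onset_s", "offset_s", "label",
            "fundamental_hz", "amplitude_sd"]
    merged = []
    bych: dict[str, list] = {}
    for cid, a, b, f, k in rows:
        bych.setdefault(cid, []).append((a, b, f, k))
    for cid, evs in bych.items():
        evs.sort()
        cur = None
        for a, b, f, k in evs:
            if cur is not None and a - cur[1] < TRUTH_MERGE_GAP_S:
                cur[1] = max(cur[1], b)
            else:
                if cur is not None:
                    merged.append((animal_id, cid, cur[0], cur[1], "ictal",
                                   cur[2], cur[3]))
                cur = [a, b, f, k]
        if cur is not None:
            merged.append((animal_id, cid, cur[0], cur[1], "ictal",
                           cur[2], cur[3]))
    df = pd.DataFrame(merged, columns=cols)
    return df.sort_values(["animal_id", "channel_id", "onset_s"],
                          kind="stable").reset_index(drop=True)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= low:
            return float(v)
    return low


def gen_cohort(cfg: SynthCohortConfig,
               ) -> tuple[dict[str, Recording], GroundTruth, pd.DataFrame]:
    """Generate a two-group cohort of recordings with ground truth.

    Each animal gets a baseline period followed by a post-injection window.
    The first event occurs at a truncated-normal latency after injection;
    the total event count over the post window is Poisson with the group
    rate; further events are placed uniformly. Returns (recordings keyed by
    animal id, ground truth, group table).
    """
    ss = np.random.SeedSequence(cfg.seed)
    total = cfg.duration_baseline + cfg.duration_post
    recordings: dict[str, Recording] = {}
    truth_frames = []
    group_rows = []
    children = ss.spawn(2 * cfg.n_animals_per_group)
    idx = 0
    for g, label in enumerate(cfg.group_labels):
        rate = cfg.seizure_rate[g]
        dmean, dsd = cfg.duration_dist[g]
        lmean, lsd = cfg.latency_dist[g]
        amp_sd = cfg.ictal_amplitude_sd[g]
        gain = cfg.band_gain[g]
        for a in range(cfg.n_animals_per_group):
            rng = np.random.default_rng(children[idx])
            idx += 1
            animal = f"{label}-{a:02d}"
            rec = gen_background(
                cfg.fs, total, cfg.n_channels, cfg.pink_exponent,
                cfg.line_amp, seed=rng, band_gain=gain or None,
                target_rms=cfg.background_rms)
            n_events = rng.poisson(rate * cfg.duration_post / 3600.0)
            schedule = []
            if n_events > 0:
                onsets = []
                first = cfg.duration_baseline + _truncnorm(rng, lmean, lsd, 0.0)
                durs = [_truncnorm(rng, dmean, dsd, MIN_EVENT_DURATION_S)
                        for _ in range(n_events)]
                if first + durs[0] < total:
                    onsets.append(first)
                for d in durs[len(onsets):]:
                    for _ in range(100):
                        o = rng.uniform(cfg.duration_baseline, total - d)
                        if all(o + d < oo or o > oo + dd
                               for oo, dd in zip(onsets, durs)):
                            onsets.append(o)
                            break
                fund = rng.uniform(*cfg.ictal_freq_range, size=len(onsets))
                for o, d, f in zip(onsets, durs, fund):
                    for cid in rec.channel_ids:
                        schedule.append((cid, o, d, float(f), amp_sd))
            rec, gt = inject_events(rec, schedule,
                                    seed=int(rng.integers(2 ** 31)))
            gt.events["animal_id"] = animal
            recordings[animal] = rec
            truth_frames.append(gt.events)
            group_rows.append((animal, label))
    truth_frames = [f for f in truth_frames if not f.empty]
    events = pd.concat(truth_frames, ignore_index=True) if truth_frames \
        else _merge_truth([])
    events = events.sort_values(["animal_id", "channel_id", "onset_s"],
                                kind="stable").reset_index(drop=True)
    groups = pd.DataFrame(group_rows, columns=["animal_id", "group"])
    params = {"config": replace(cfg), "injection_time_s": cfg.duration_baseline}
    return recordings, GroundTruth(events, params), groups


def gen_survival_cohort(n_per_group: int, hazards: tuple[float, float],
                        max_steps: int, seed: int = 0,
                        group_labels: tuple[str, str] = ("WT-like", "KO-like"),
                        step_min: float = 30.0) -> pd.DataFrame:
    """Discrete-time survival cohort for the repeated-injection threshold
    test: each 30-minute dosing step carries a per-group hazard of reaching
    the clinical-seizure endpoint; animals with no event by ``max_steps``
    are censored at ``max_steps * 30`` minutes.

    Returns a frame with columns animal_id, group, time_min, event.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    for h in hazards:
        if not 0 <= h <= 1:
            raise ValueError(f"hazard {h} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for g, label in enumerate(group_labels):
        h = hazards[g]
        for a in range(n_per_group):
            draws = rng.random(max_steps)
            hit = np.flatnonzero(draws < h)
            if hit.size:
                rows.append((f"{label}-{a:02d}", label,
                             (hit[0] + 1) * step_min, True))
            else:
                rows.append((f"{label}-{a:02d}", label,
                             max_steps * step_min, False))
    return pd.DataFrame(rows, columns=["animal_id", "group", "time_min",
                                       "event"])
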