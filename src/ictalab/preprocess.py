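"""Signal conditioning and baseline statistics.

The detector and the dB normalization both reference a baseline interval:
seizures are intervals where the sliding-window RMS envelope exceeds the
baseline RMS mean by a multiple of the baseline RMS standard deviation.
The SD is taken over the sliding-RMS series itself (not raw samples), so
the threshold is expressed in units of the envelope's own variability.

Defaults: 1 s RMS windows with 0.5 s step (resolves events of >5 s), 50 Hz
zero-phase IIR notch at Q=30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import Recording

__all__ = [
    "BaselineStats",
    "notch_filter",
    "resample",
    "sliding_rms",
    "compute_baseline_stats",
]


@dataclass
class BaselineStats:
    """Per-channel reference statistics of the sliding-RMS envelope.

    ``rms_mean`` and ``rms_sd`` are in µV; ``spectral_ref`` (per-frequency
    baseline power, filled by :func:`ictalab.tfr.baseline_power`) is keyed
    by channel and aligned with a wavelet family's frequency axis.
    """

    channel_ids: list[str]
    rms_mean: np.ndarray        # (n_channels,) µV
    rms_sd: np.ndarray          # (n_channels,) µV
    window: float               # s
    step: float                 # s
    interval: tuple[float, float]
    spectral_ref: dict[str, np.ndarray] = field(default_factory=dict)

    def threshold(self, k: float) -> np.ndarray:
        """Detection threshold ``rms_mean + k * rms_sd`` per channel (µV)."""
        return self.rms_mean + k * self.rms_sd

    def for_channel(self, channel_id: str) -> tuple[float, float]:
        i = self.channel_ids.index(channel_id)
        return float(self.rms_mean[i]), float(self.rms_sd[i])


def notch_filter(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch removing power-line interference.

    Forward-backward filtering keeps event onsets unshifted; attenuation at
    ``freq`` exceeds 20 dB while tones outside ``freq ± freq/q`` pass with
    under ~1 dB ripple.
    """
    nyq = rec.fs / 2
    if not 0 < freq < nyq:
        raise ValueError(f"notch frequency {freq} Hz outside (0, {nyq}) Hz")
    b, a = sps.iirnotch(freq, q, fs=rec.fs)
    out = rec.copy()
    out.samples = sps.filtfilt(b, a, rec.samples, axis=-1)
    return out


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling to ``target_fs``; identity when rates match."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if rec.n_samples < 2:
        raise ValueError("recording too short to resample (need >= 2 samples)")
    if np.isclose(target_fs, rec.fs):
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = rec.copy()
    out.samples = sps.resample_poly(rec.samples, frac.numerator,
                                    frac.denominator, axis=-1)
    out.fs = rec.fs * frac.numerator / frac.denominator
    return out


def sliding_rms(x: np.ndarray, fs: float, window: float = 1.0,
                step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window RMS envelope of a 1-D signal.

    Returns window-center times (s) and RMS values. ``rms[i]`` is the root
    mean square over ``window`` seconds starting at ``i * step``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sliding_rms expects a 1-D signal")
    wlen = int(round(window * fs))
    slen = int(round(step * fs))
    if wlen < 1:
        raise ValueError("window shorter than one sample")
    if slen < 1 or slen > wlen:
        raise ValueError("step must satisfy 1/fs <= step <= window")
    if wlen > x.size:
        raise ValueError(f"window ({wlen} samples) longer than signal ({x.size})")
    # O(n) via cumulative sum of squares
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, x.size - wlen + 1, slen)
    ms = (csum[starts + wlen] - csum[starts]) / wlen
    rms = np.sqrt(np.maximum(ms, 0.0))
    times = (starts + wlen / 2) / fs
    return times, rms


def compute_baseline_stats(rec: Recording, interval: tuple[float, float],
                           window: float = 1.0, step: float = 0.5,
                           min_windows: int = 10) -> BaselineStats:
    """Mean/SD of the sliding-RMS envelope over a baseline interval.

    The interval must fit inside the recording and span at least
    ``min_windows`` full RMS windows.
    """
    t0, t1 = interval
    if not (0 <= t0 < t1 <= rec.duration + 1e-9):
        raise ValueError(
            f"baseline interval {interval} outside recording (0, {rec.duration:.1f}) s"
        )
    n_windows = int((t1 - t0 - window) / step) + 1
    if n_windows < min_windows:
        raise ValueError(
            f"baseline interval spans {n_windows} windows; need >= {min_windows}"
        )
    i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
    means = np.empty(rec.n_channels)
    sds = np.empty(rec.n_channels)
    for c in range(rec.n_channels):
        _, rms = sliding_rms(rec.samples[c, i0:i1], rec.fs, window, step)
        means[c] = rms.mean()
        sds[c] = rms.std(ddof=1)
    return BaselineStats(list(rec.channel_ids), means, sds, window, step, (t0, t1))
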