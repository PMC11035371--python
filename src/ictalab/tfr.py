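"""Complex Morlet wavelet time-frequency analysis.

Each wavelet is a complex sinusoid under a Gaussian envelope,

    w(t) = exp(i 2 pi f t) * exp(-t^2 / (2 sigma^2)),   sigma = n / (2 pi f),

where the cycle count ``n`` ramps linearly (default 1 -> 30) across the
frequency axis (default 1 -> 200 Hz in 200 steps), trading temporal for
spectral precision along the axis. Convolution is carried out in the
frequency domain (FFT); each wavelet's spectrum is max-normalized so that
a unit-amplitude tone at a bin frequency yields unit coefficient magnitude
(analytic-signal convention: the normalized kernel is scaled by 2 because
a real tone splits its amplitude between positive and negative
frequencies). Power is the magnitude |W| of the coefficients by default
("squared" mode, |W|^2, is available and recorded in the output).

Power is expressed in dB relative to a per-frequency baseline reference:
dB = 10 log10(P / P_baseline). Trials are epoched relative to seizure
onset (-5..40 s for depth LFP, -5..30 s for the 30-channel skull array).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import BaselineStats
from .signal_io import Recording

__all__ = [
    "BANDS",
    "BANDS_INTRAHIPPOCAMPAL",
    "WaveletFamily",
    "TFRStack",
    "build_wavelet_family",
    "wavelet_kernels",
    "wavelet_transform",
    "extract_power",
    "baseline_power",
    "power_db",
    "epoch_trials",
    "tfr_stack",
    "band_power",
    "aggregate",
    "eeg_metrics",
]

logger = logging.getLogger(__name__)

# canonical EEG bands (Hz, inclusive bounds on the frequency axis)
BANDS: dict[str, tuple[float, float]] = {
    "global": (1.0, 200.0),
    "delta": (1.0, 3.0),
    "theta": (4.0, 8.0),
    "alpha": (9.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 80.0),
    "hfo": (81.0, 200.0),
}

# intrahippocampal (subdural, 2 kHz) context
BANDS_INTRAHIPPOCAMPAL: dict[str, tuple[float, float]] = {
    "global": (1.0, 500.0),
    "theta": (4.0, 8.0),
    "hfo": (80.0, 500.0),
}


@dataclass
class WaveletFamily:
    freqs: np.ndarray       # Hz, strictly increasing
    cycles: np.ndarray      # n per frequency
    sigmas: np.ndarray      # s, n / (2 pi f)
    fs: float
    kernel_length: int      # samples, odd

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.freqs) > 0), "freqs must be increasing"
        assert self.kernel_length % 2 == 1


def build_wavelet_family(fmin: float = 1.0, fmax: float = 200.0,
                         n_steps: int = 200, cycle_min: float = 1.0,
                         cycle_max: float = 30.0, fs: float = 1000.0,
                         ) -> WaveletFamily:
    """Linearly spaced frequencies with a linear cycle ramp.

    ``sigma_i = cycles_i / (2 pi freqs_i)`` exactly; the shared kernel
    length is odd and covers at least +-3 sigma of the widest wavelet.
    """
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    if fmax >= fs / 2:
        raise ValueError(f"fmax {fmax} Hz at or above Nyquist ({fs / 2} Hz)")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    freqs = np.linspace(fmin, fmax, n_steps)
    cycles = np.linspace(cycle_min, cycle_max, n_steps)
    sigmas = cycles / (2 * np.pi * freqs)
    klen = int(np.ceil(6 * sigmas.max() * fs))
    klen += 1 - klen % 2  # odd
    klen = max(klen, 3)
    return WaveletFamily(freqs, cycles, sigmas, fs, klen)


def wavelet_kernels(family: WaveletFamily) -> np.ndarray:
    """Normalized complex kernels, shape (n_freqs, kernel_length).

    Each kernel's spectrum peaks at 2 (analytic-signal gain), so
    convolution with a real unit tone at the kernel's center frequency
    gives coefficient magnitude ~1.
    """
    L = family.kernel_length
    t = (np.arange(L) - (L - 1) / 2) / family.fs
    k = np.exp(2j * np.pi * family.freqs[:, None] * t[None, :])
    k *= np.exp(-(t[None, :] ** 2) / (2 * family.sigmas[:, None] ** 2))
    nfft = spfft.next_fast_len(8 * L)
    gain = np.abs(spfft.fft(k, nfft, axis=1)).max(axis=1)
    return 2 * k / gain[:, None]


def wavelet_transform(x: np.ndarray, family: WaveletFamily,
                      kernels: np.ndarray | None = None) -> np.ndarray:
    """FFT-domain convolution with every wavelet in the family.

    The signal is reflection-padded by 3 sigma_max of samples on each side
    (trimmed afterwards) so edges carry no fabricated power. Returns
    complex coefficients of shape (n_freqs, len(x)).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("wavelet_transform expects a 1-D signal")
    if x.size < family.kernel_length:
        raise ValueError(
            f"signal ({x.size} samples) shorter than kernel "
            f"({family.kernel_length} samples)"
        )
    if kernels is None:
        kernels = wavelet_kernels(family)
    pad = int(np.ceil(3 * family.sigmas.max() * family.fs))
    xp = np.pad(x, pad, mode="reflect")
    n, L = xp.size, family.kernel_length
    nfft = spfft.next_fast_len(n + L - 1)
    X = spfft.fft(xp, nfft)
    K = spfft.fft(kernels, nfft, axis=1)
    full = spfft.ifft(K * X[None, :], axis=1)
    start = (L - 1) // 2  # center-aligned, as in "same"-mode convolution
    coefs = full[:, start: start + n]
    return coefs[:, pad: pad + x.size]


def extract_power(coefs: np.ndarray, units: str = "magnitude") -> np.ndarray:
    """Power from complex coefficients: |W| (default) or |W|^2."""
    if units == "magnitude":
        return np.abs(coefs)
    if units == "squared":
        return np.abs(coefs) ** 2
    raise ValueError(f"units must be 'magnitude' or 'squared', got {units!r}")


def baseline_power(rec: Recording, interval: tuple[float, float],
                   family: WaveletFamily, channel: str | None = None,
                   units: str = "magnitude",
                   stats: BaselineStats | None = None) -> np.ndarray:
    """Time-averaged wavelet power over a baseline interval, per frequency.

    Serves as the dB reference for later trials. When ``stats`` is given
    the vector is also stored in ``stats.spectral_ref[channel]``. For a
    multichannel recording pass ``channel``; a (n_channels, n_freqs) array
    is returned when it is omitted.
    """
    t0, t1 = interval
    support = family.kernel_length / family.fs
    if t1 - t0 < 10 * support:
        raise ValueError(
            f"baseline interval {t1 - t0:.1f} s shorter than 10 wavelet "
            f"supports ({10 * support:.1f} s)"
        )
    if not (0 <= t0 < t1 <= rec.duration + 1e-9):
        raise ValueError("baseline interval outside recording")
    i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
    kernels = wavelet_kernels(family)
    chans = [channel] if channel is not None else list(rec.channel_ids)
    refs = np.empty((len(chans), family.freqs.size))
    for row, cid in enumerate(chans):
        ci = rec.channel_index(cid)
        W = wavelet_transform(rec.samples[ci, i0:i1], family, kernels)
        refs[row] = extract_power(W, units).mean(axis=1)
        if stats is not None:
            stats.spectral_ref[cid] = refs[row]
    return refs[0] if channel is not None else refs


def power_db(P: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Decibel conversion ``10 log10(P / reference)`` per frequency.

    ``reference`` is broadcast along the frequency axis (the second-to-last
    axis of a trials x freqs x time stack, the first of a freqs x time map).
    """
    reference = np.asarray(reference, dtype=np.float64)
    if np.any(reference <= 0):
        raise ValueError("dB reference must be strictly positive")
    P = np.asarray(P, dtype=np.float64)
    ref = reference.reshape((-1, 1)) if P.ndim >= 2 else reference
    with np.errstate(divide="ignore"):
        return 10 * np.log10(P / ref)


def epoch_trials(rec: Recording, events: list, window: tuple[float, float],
                 channel: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Cut onset-aligned raw-signal trials around each event.

    ``window = (pre, post)`` in seconds relative to onset (pre negative,
    e.g. ``(-5, 40)``); each trial has ``round((post - pre) * fs) + 1``
    samples. Trials extending past the recording bounds are dropped and
    logged. Returns (trials, time axis, kept events).
    """
    if not events:
        raise ValueError("no events to epoch")
    pre, post = window
    if post <= pre:
        raise ValueError("window must satisfy post > pre")
    ci = rec.channel_index(channel)
    n = int(round((post - pre) * rec.fs)) + 1
    trials, kept = [], []
    for ev in events:
        onset = ev.onset if hasattr(ev, "onset") else float(ev[0])
        i0 = int(round((onset + pre) * rec.fs))
        if i0 < 0 or i0 + n > rec.n_samples:
            logger.info("dropping trial at %.1f s: window out of bounds", onset)
            continue
        trials.append(rec.samples[ci, i0: i0 + n])
        kept.append(ev)
    if not trials:
        raise ValueError("all trials fell outside the recording")
    times = pre + np.arange(n) / rec.fs
    return np.asarray(trials), times, kept


@dataclass
class TFRStack:
    """Onset-aligned trials x frequencies x time wavelet power."""

    power: np.ndarray           # (n_trials, n_freqs, n_times), linear units
    times: np.ndarray           # s relative to onset
    freqs: np.ndarray           # Hz
    units: str                  # "magnitude" | "squared"
    baseline_ref: np.ndarray | None = None   # (n_freqs,)
    channel_id: str | None = None
    animal_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def db(self) -> np.ndarray:
        if self.baseline_ref is None:
            raise ValueError("no baseline reference attached")
        return power_db(self.power, self.baseline_ref)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power, compression="gzip")
            f.create_dataset("times", data=self.times)
            f.create_dataset("freqs", data=self.freqs)
            if self.baseline_ref is not None:
                f.create_dataset("baseline_ref", data=self.baseline_ref)
            f.attrs["units"] = self.units
            if self.channel_id is not None:
                f.attrs["channel_id"] = self.channel_id
            if self.animal_ids is not None:
                f.create_dataset("animal_ids",
                                 data=np.array(self.animal_ids, dtype="S"))

    @classmethod
    def from_hdf5(cls, path) -> "TFRStack":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                power=f["power"][()],
                times=f["times"][()],
                freqs=f["freqs"][()],
                units=f.attrs["units"],
                baseline_ref=f["baseline_ref"][()] if "baseline_ref" in f else None,
                channel_id=f.attrs.get("channel_id"),
                animal_ids=[s.decode() for s in f["animal_ids"][()]]
                if "animal_ids" in f else None,
            )


def tfr_stack(rec: Recording, events: list, family: WaveletFamily,
              window: tuple[float, float], channel: str,
              baseline_ref: np.ndarray | None = None,
              units: str = "magnitude",
              animal_id: str | None = None) -> TFRStack:
    """Wavelet power for every onset-aligned trial of one channel."""
    trials, times, kept = epoch_trials(rec, events, window, channel)
    kernels = wavelet_kernels(family)
    power = np.empty((len(trials), family.freqs.size, trials.shape[1]))
    for i, tr in enumerate(trials):
        power[i] = extract_power(wavelet_transform(tr, family, kernels), units)
    return TFRStack(
        power=power, times=times, freqs=family.freqs, units=units,
        baseline_ref=baseline_ref, channel_id=channel,
        animal_ids=[animal_id] * len(trials) if animal_id else None,
        meta={"n_events_in": len(events), "n_trials": len(trials)},
    )


def band_power(stack: TFRStack, band: tuple[float, float], db: bool = True,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Band-collapsed power per trial.

    Averages over frequency bins inside ``band`` (inclusive) giving a
    (trials, time) series, then over the post-onset portion (time >= 0)
    giving one scalar per trial. ``db=True`` converts against the stack's
    baseline reference first.
    """
    low, high = band
    sel = (stack.freqs >= low) & (stack.freqs <= high)
    if not np.any(sel):
        raise ValueError(f"band {band} empty on axis "
                         f"[{stack.freqs[0]}, {stack.freqs[-1]}] Hz")
    data = stack.db() if db else stack.power
    series = data[:, sel, :].mean(axis=1)
    scalars = series[:, stack.times >= 0].mean(axis=1)
    return series, scalars


def aggregate(table, mode: str = "per_seizure"):
    """Collapse a per-trial table to the analysis unit.

    ``table`` is tidy with one row per trial: an ``animal_id`` column,
    optionally a ``channel_id`` column, and numeric value columns.
    ``per_seizure`` keeps one row per trial (depth-LFP convention);
    ``per_animal`` averages trials within animal — and across channels
    when present — first (skull-array convention).
    """
    import pandas as pd

    df = pd.DataFrame(table)
    if mode == "per_seizure":
        return df.reset_index(drop=True)
    if mode != "per_animal":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if "animal_id" not in df.columns:
        raise ValueError("per_animal aggregation needs an animal_id column")
    keys = ["animal_id"]
    if "group" in df.columns:
        keys.append("group")
    num = df.select_dtypes("number").columns
    return df.groupby(keys, sort=True)[list(num)].mean().reset_index()


def eeg_metrics(segment: np.ndarray, fs: float) -> dict[str, float]:
    """Auxiliary descriptive EEG metrics of one segment.

    Returns standard deviation, zero-crossing rate (crossings/s), RMS,
    excess kurtosis, skewness, spectral entropy (Shannon entropy of the
    normalized Welch PSD, nats) and total spectral power (PSD integral,
    µV²). Kurtosis/skewness/entropy are NaN for a constant segment.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size < fs:
        raise ValueError("segment must be at least 1 s long")
    sd = float(np.std(x))
    rms = float(np.sqrt(np.mean(x * x)))
    sign = np.sign(x)
    sign[sign == 0] = 1
    zcr = float(np.count_nonzero(np.diff(sign)) / (x.size / fs))
    if sd == 0:
        kurt = skew = entropy = total = np.nan
        if np.all(x == 0):
            total = 0.0
    else:
        kurt = float(spstats.kurtosis(x, fisher=True))
        skew = float(spstats.skew(x))
        nperseg = min(int(round(fs)), x.size)
        freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg,
                               noverlap=nperseg // 2)
        total = float(np.trapezoid(psd, freqs))
        p = psd / psd.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
    return {
        "sd": sd, "zero_crossing_rate": zcr, "rms": rms,
        "kurtosis": kurt, "skewness": skew,
        "spectral_entropy": entropy, "total_power": total,
    }
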