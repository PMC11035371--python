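"""Recording, layout and event-table I/O.

All voltages are microvolts (µV) internally; times are seconds from
recording start. Event intervals are half-open ``[onset, offset)`` so that
``duration = offset - onset`` and adjacent events do not share samples.

Three on-disk formats are supported:

* plain EDF (European Data Format, 16-bit) for continuous recordings,
* little-endian float32 binary with a ``key: value`` text sidecar
  (a lossless, language-neutral fixture format),
* tab-separated text for channel layouts and event tables.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ChannelLayout",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_layout",
    "write_layout",
    "read_events",
    "write_events",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["animal_id", "channel_id", "onset_s", "offset_s", "label"]


class FormatError(ValueError):
    """A file failed to parse as the declared format."""


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Unique channel labels, ordered as the rows of ``samples``.
    start_time : float
        Recording-relative start, seconds (0 for synthetic data).
    annotations : list of (onset_s, offset_s, label)
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str]
    start_time: float = 0.0
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_ids)} channel ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel {channel_id!r}") from None

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(), self.fs, list(self.channel_ids),
            self.start_time, list(self.annotations),
        )


@dataclass
class ChannelLayout:
    """Planar skull coordinates (mm) per channel id."""

    positions: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for cid, (x, y) in self.positions.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinate for channel {cid!r}")

    def coords(self, channel_ids: list[str]) -> np.ndarray:
        missing = [c for c in channel_ids if c not in self.positions]
        if missing:
            raise ValueError(f"channels missing from layout: {missing}")
        return np.array([self.positions[c] for c in channel_ids], dtype=float)

    def __len__(self) -> int:
        return len(self.positions)


def grid_layout(n_rows: int = 5, n_cols: int = 6, pitch_mm: float = 1.0) -> ChannelLayout:
    """Default rectangular array layout (30 channels at 5x6 by default)."""
    pos = {}
    for r in range(n_rows):
        for c in range(n_cols):
            pos[f"ch{r * n_cols + c}"] = (c * pitch_mm, r * pitch_mm)
    return ChannelLayout(pos)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------
# Plain EDF: 256-byte fixed header, 256 bytes per signal, then data records
# of 16-bit little-endian integers mapped linearly from [dig_min, dig_max]
# to [phys_min, phys_max]. One-second records are used on write.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics to fit the fixed-width ASCII field
        s = f"{float(value):.{max(width - 8, 1)}g}"[:width]
    return s.ljust(width).encode("ascii")


def write_recording(rec: Recording, path, format: str = "edf") -> None:
    """Write a recording as EDF or binary+sidecar.

    EDF quantizes to 16 bits over a symmetric physical range covering the
    data; binary round-trips float32 exactly.
    """
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ValueError("cannot write an empty recording")
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("samples contain NaN or Inf")
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
    elif format == "binary":
        _write_binary(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path, format: str | None = None) -> Recording:
    """Read an EDF or binary+sidecar recording; format inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "binary"
    if format == "edf":
        return _read_edf(path)
    if format == "binary":
        return _read_binary(path)
    raise ValueError(f"unknown format {format!r}")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nchan = rec.n_channels
    # symmetric physical range; EDF requires phys_min != phys_max
    amax = float(np.max(np.abs(rec.samples)))
    phys_max = max(amax, 1.0) * 1.0000001
    phys_min = -phys_max
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)

    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((nchan, n_records * fs))
    padded[:, : rec.n_samples] = rec.samples
    digital = np.round((padded - phys_min) * scale + _EDF_DIG_MIN).astype("<i2")
    if np.any(digital > _EDF_DIG_MAX) or np.any(digital < _EDF_DIG_MIN):
        raise ValueError("samples exceed representable EDF range after scaling")

    header_bytes = 256 * (1 + nchan)
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))                    # version
        f.write(_edf_field("X X X X", 80))             # patient id
        f.write(_edf_field("Startdate X", 80))         # recording id
        f.write(_edf_field("01.01.00", 8))             # start date
        f.write(_edf_field("00.00.00", 8))             # start time
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("", 44))                    # reserved
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field(1, 8))                      # record duration (s)
        f.write(_edf_field(nchan, 4))
        for cid in rec.channel_ids:
            f.write(_edf_field(cid, 16))
        for _ in range(nchan):
            f.write(_edf_field("", 80))                # transducer
        for _ in range(nchan):
            f.write(_edf_field("uV", 8))               # physical dimension
        for _ in range(nchan):
            f.write(_edf_field(f"{phys_min:.6f}"[:8], 8))
        for _ in range(nchan):
            f.write(_edf_field(f"{phys_max:.6f}"[:8], 8))
        for _ in range(nchan):
            f.write(_edf_field(_EDF_DIG_MIN, 8))
        for _ in range(nchan):
            f.write(_edf_field(_EDF_DIG_MAX, 8))
        for _ in range(nchan):
            f.write(_edf_field("", 80))                # prefiltering
        for _ in range(nchan):
            f.write(_edf_field(fs, 8))                 # samples per record
        for _ in range(nchan):
            f.write(_edf_field("", 32))                # reserved
        # data records: per record, all samples of ch0, then ch1, ...
        for r in range(n_records):
            f.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def _edf_read_field(f, width: int) -> str:
    raw = f.read(width)
    if len(raw) < width:
        raise FormatError("truncated EDF header")
    return raw.decode("ascii", errors="replace").strip()


def _read_edf(path: Path) -> Recording:
    with open(path, "rb") as f:
        _edf_read_field(f, 8)       # version
        _edf_read_field(f, 80)
        _edf_read_field(f, 80)
        _edf_read_field(f, 8)
        _edf_read_field(f, 8)
        _edf_read_field(f, 8)       # header bytes
        _edf_read_field(f, 44)
        try:
            n_records = int(_edf_read_field(f, 8))
            record_dur = float(_edf_read_field(f, 8))
            nchan = int(_edf_read_field(f, 4))
        except ValueError as e:
            raise FormatError(f"malformed EDF header counts: {e}") from None
        if nchan <= 0 or n_records < 0:
            raise FormatError("malformed EDF header: non-positive signal/record count")

        def fields(width, conv=str):
            out = []
            for _ in range(nchan):
                raw = _edf_read_field(f, width)
                try:
                    out.append(conv(raw))
                except ValueError:
                    raise FormatError(
                        f"malformed EDF header field {raw!r}"
                    ) from None
            return out

        labels = fields(16)
        fields(80)
        fields(8)                                   # physical dimension
        phys_min = fields(8, float)
        phys_max = fields(8, float)
        dig_min = fields(8, int)
        dig_max = fields(8, int)
        fields(80)
        spr = fields(8, int)                        # samples per record
        fields(32)

        if len(set(spr)) != 1:
            raise FormatError("mixed per-channel sampling rates are unsupported")
        spr0 = spr[0]
        fs = spr0 / record_dur
        data = f.read()
    expected = n_records * nchan * spr0 * 2
    if len(data) < expected:
        raise FormatError(
            f"truncated EDF data: expected {expected} bytes, got {len(data)}"
        )
    digital = np.frombuffer(data[:expected], dtype="<i2").astype(np.int64)
    digital = digital.reshape(n_records, nchan, spr0)
    samples = np.concatenate([digital[:, i, :].ravel()[None, :] for i in range(nchan)])
    out = np.empty(samples.shape, dtype=np.float64)
    for i in range(nchan):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        out[i] = (samples[i] - dig_min[i]) * gain + phys_min[i]
    return Recording(out, fs, labels)


# ---------------------------------------------------------------------------
# binary + sidecar
# ---------------------------------------------------------------------------

def _write_binary(rec: Recording, path: Path) -> None:
    data = rec.samples.astype("<f4")
    path.write_bytes(data.tobytes())
    sidecar = path.with_suffix(path.suffix + ".meta")
    lines = [
        f"fs: {rec.fs!r}",
        f"n_channels: {rec.n_channels}",
        f"n_samples: {rec.n_samples}",
        f"channel_ids: {','.join(rec.channel_ids)}",
        "dtype: float32",
        "byte_order: little",
        f"start_time: {rec.start_time!r}",
    ]
    sidecar.write_text("\n".join(lines) + "\n")


def _read_binary(path: Path) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".meta")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = {}
    for line in sidecar.read_text().splitlines():
        if not line.strip():
            continue
        if ":" not in line:
            raise FormatError(f"malformed sidecar line {line!r}")
        k, v = line.split(":", 1)
        meta[k.strip()] = v.strip()
    try:
        fs = float(meta["fs"])
        nchan = int(meta["n_channels"])
        nsamp = int(meta["n_samples"])
        channel_ids = meta["channel_ids"].split(",")
    except (KeyError, ValueError) as e:
        raise FormatError(f"malformed sidecar: {e}") from None
    raw = path.read_bytes()
    if len(raw) < nchan * nsamp * 4:
        raise FormatError("truncated binary data")
    samples = np.frombuffer(raw, dtype="<f4", count=nchan * nsamp)
    samples = samples.reshape(nchan, nsamp).astype(np.float64)
    return Recording(samples, fs, channel_ids,
                     start_time=float(meta.get("start_time", 0.0)))


# ---------------------------------------------------------------------------
# layouts and event tables (TSV)
# ---------------------------------------------------------------------------

def write_layout(layout: ChannelLayout, path) -> None:
    df = pd.DataFrame(
        [(cid, x, y) for cid, (x, y) in layout.positions.items()],
        columns=["channel_id", "x_mm", "y_mm"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_layout(path) -> ChannelLayout:
    df = pd.read_csv(path, sep="\t")
    for col in ("channel_id", "x_mm", "y_mm"):
        if col not in df.columns:
            raise FormatError(f"layout file missing column {col!r}")
    if df["channel_id"].duplicated().any():
        dup = df.loc[df["channel_id"].duplicated(), "channel_id"].iloc[0]
        raise FormatError(f"duplicate channel id {dup!r} in layout")
    return ChannelLayout(
        {str(r.channel_id): (float(r.x_mm), float(r.y_mm)) for r in df.itertuples()}
    )


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table; extra columns beyond the core five are kept."""
    df = events.copy()
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"event table missing column {col!r}")
    core = [c for c in EVENT_COLUMNS]
    extras = [c for c in df.columns if c not in core]
    df = df[core + extras]
    df = df.sort_values(["animal_id", "channel_id", "onset_s"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "channel_id": str})
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"event table missing column {col!r}")
    if len(df) and not (df["offset_s"] > df["onset_s"]).all():
        bad = df[df["offset_s"] <= df["onset_s"]].iloc[0]
        raise FormatError(
            f"event with offset <= onset: {bad['onset_s']}..{bad['offset_s']}"
        )
    return df.sort_values(
        ["animal_id", "channel_id", "onset_s"], kind="stable"
    ).reset_index(drop=True)
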