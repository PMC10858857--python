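"""Reading and writing European Data Format (EDF) signal files.

EDF stores a 256-byte ASCII header, one 256-byte ASCII block per signal,
and interleaved data records of 16-bit little-endian integers mapped
linearly between a digital and a physical range.  Per-channel sample
rates are expressed as samples-per-record and are preserved exactly on
read, which the downstream pipeline relies on (UCDDB mixes 128 Hz EEG
with 64 Hz EMG in one file).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from melstage.recording import Channel, ChannelNotFoundError, Recording, normalize_label

DIG_MIN, DIG_MAX = -32768, 32767


class CorruptHeaderError(ValueError):
    """The file does not parse as a standard EDF header."""


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    rec: Recording,
    record_duration_s: float = 1.0,
    physical_dim: str = "uV",
) -> None:
    """Write a recording as a 16-bit EDF file.

    Every channel's ``fs * record_duration_s`` must be an integer (true
    for the 125/128/64 Hz rates handled here with 1-s records).  The
    physical range per channel is taken from the data, so the round-trip
    error is bounded by the 16-bit quantization of that range.
    """
    path = Path(path)
    n_records = int(np.floor(rec.duration_s / record_duration_s))
    spr: list[int] = []
    for ch in rec.channels:
        n = ch.fs * record_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"channel {ch.label!r}: fs={ch.fs} Hz does not fit an integer "
                f"number of samples in a {record_duration_s}-s record"
            )
        spr.append(int(round(n)))

    phys_ranges = []
    digitized = []
    for ch, n in zip(rec.channels, spr):
        x = ch.samples[: n * n_records]
        pmin, pmax = float(np.min(x)), float(np.max(x))
        if pmax <= pmin:  # flat signal: widen to a valid range
            pmax = pmin + 1.0
        scale = (pmax - pmin) / (DIG_MAX - DIG_MIN)
        dig = np.round((x - pmin) / scale + DIG_MIN).astype("<i2")
        phys_ranges.append((pmin, pmax))
        digitized.append(dig.reshape(n_records, n))

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(rec.subject_id or "X", 80),
            _field("Startdate 01-JAN-2000", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + len(rec.channels))), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field(f"{record_duration_s:g}", 8),
            _field(str(len(rec.channels)), 4),
        ]
    )
    sig_fields = []
    for getter, width in [
        (lambda i: rec.channels[i].label, 16),
        (lambda i: "", 80),
        (lambda i: physical_dim, 8),
        (lambda i: f"{phys_ranges[i][0]:.8g}"[:8], 8),
        (lambda i: f"{phys_ranges[i][1]:.8g}"[:8], 8),
        (lambda i: str(DIG_MIN), 8),
        (lambda i: str(DIG_MAX), 8),
        (lambda i: "", 80),
        (lambda i: str(spr[i]), 8),
        (lambda i: "", 32),
    ]:
        for i in range(len(rec.channels)):
            sig_fields.append(_field(getter(i), width))

    with open(path, "wb") as f:
        f.write(header)
        f.write(b"".join(sig_fields))
        for r in range(n_records):
            for dig in digitized:
                f.write(dig[r].tobytes())


def _read_ascii(buf: bytes, pos: int, width: int) -> tuple[str, int]:
    return buf[pos : pos + width].decode("ascii", errors="replace").strip(), pos + width


def read_edf(
    path: str | Path,
    wanted_channels: Optional[Sequence[str]] = None,
    subject_id: Optional[str] = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Channel labels are matched case-insensitively with separator
    normalization, so requesting ``"C4A1"`` resolves a stored ``"C4-A1"``.
    Native per-channel sample rates and physical units are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = path.read_bytes()
    if len(raw) < 256:
        raise CorruptHeaderError(f"{path}: file shorter than an EDF header (256 bytes)")

    pos = 0
    _ver, pos = _read_ascii(raw, pos, 8)
    patient, pos = _read_ascii(raw, pos, 80)
    _recording, pos = _read_ascii(raw, pos, 80)
    _date, pos = _read_ascii(raw, pos, 8)
    _time, pos = _read_ascii(raw, pos, 8)
    try:
        header_bytes = int(raw[pos : pos + 8])
        pos += 8
        _reserved, pos = _read_ascii(raw, pos, 44)
        n_records = int(raw[pos : pos + 8])
        pos += 8
        record_dur = float(raw[pos : pos + 8])
        pos += 8
        n_signals = int(raw[pos : pos + 4])
        pos += 4
    except ValueError as e:
        raise CorruptHeaderError(f"{path}: non-numeric EDF header field ({e})") from e
    if n_signals <= 0 or record_dur <= 0 or n_records < 0:
        raise CorruptHeaderError(
            f"{path}: implausible header (n_signals={n_signals}, "
            f"record_duration={record_dur}, n_records={n_records})"
        )
    if header_bytes != 256 * (1 + n_signals):
        raise CorruptHeaderError(
            f"{path}: header size field {header_bytes} != {256 * (1 + n_signals)}"
        )
    if len(raw) < header_bytes:
        raise CorruptHeaderError(f"{path}: truncated signal header block")

    def sig_block(offset: int, width: int, i: int) -> str:
        start = 256 + offset * n_signals + i * width
        return raw[start : start + width].decode("ascii", errors="replace").strip()

    labels = [sig_block(0, 16, i) for i in range(n_signals)]
    phys_min = [float(sig_block(16 + 80 + 8, 8, i)) for i in range(n_signals)]
    phys_max = [float(sig_block(16 + 80 + 8 + 8, 8, i)) for i in range(n_signals)]
    dig_min = [int(sig_block(16 + 80 + 8 + 16, 8, i)) for i in range(n_signals)]
    dig_max = [int(sig_block(16 + 80 + 8 + 24, 8, i)) for i in range(n_signals)]
    # per-signal field offsets: label 0, transducer 16, dim 96, phys_min 104,
    # phys_max 112, dig_min 120, dig_max 128, prefilter 136, spr 216
    spr = [int(sig_block(216, 8, i)) for i in range(n_signals)]

    wanted_idx = list(range(n_signals))
    if wanted_channels is not None:
        keys = {normalize_label(lb): i for i, lb in enumerate(labels)}
        wanted_idx = []
        for lb in wanted_channels:
            k = normalize_label(lb)
            if k not in keys:
                raise ChannelNotFoundError(
                    f"channel {lb!r} not in {path.name}; available: {labels}"
                )
            wanted_idx.append(keys[k])

    rec_len = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    n_avail = len(data) // rec_len if rec_len else 0
    n_records = min(n_records, n_avail)
    data = data[: n_records * rec_len].reshape(n_records, rec_len)
    offsets = np.concatenate([[0], np.cumsum(spr)])

    channels = []
    for i in wanted_idx:
        dig = data[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        phys = (dig - dig_min[i]) * scale + phys_min[i]
        channels.append(Channel(label=labels[i], samples=phys, fs=spr[i] / record_dur))
    return Recording(channels=channels, subject_id=subject_id or patient)
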