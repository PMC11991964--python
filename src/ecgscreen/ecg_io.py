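"""Reading and writing ECG signals, per-minute apnea annotations, and feature tables.

Supported dialects
------------------
* WFDB header/signal pairs (``<record>.hea`` + ``<record>.dat``), restricted to
  the flavour used by overnight single-lead apnea screening databases:
  format-16 (little-endian 16-bit two's complement) signals.  Multi-channel
  records are accepted; channel 0 is always returned, since the recordings this
  package targets are single-lead.
* WFDB binary annotation files (MIT annotation format), where per-minute apnea
  marks are stored as one annotation per minute: code 1 ('N', normal) or
  code 8 ('A', apnea/hypopnea present).
* Plain-text dialects: one sample per line for signals (CSV), one of
  ``A``/``N``/``0``/``1`` per line for annotations.  These exist so synthetic
  fixtures need no binary writer.
* Delimited feature tables with a header row (``record_id``, ``minute_index``,
  ``label``, the 18 feature columns, ``valid``); round-trip lossless.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "MinuteLabels",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_csv_signal",
    "write_csv_signal",
    "read_minute_annotations",
    "write_minute_annotations",
    "write_feature_table",
    "read_feature_table",
    "check_annotation_consistency",
]


@dataclass
class ECGRecord:
    """A single-lead ECG recording.

    Amplitudes are in mV (or an equivalent dimensionless scale); the default
    sampling rate of 100 Hz matches overnight apnea-screening recordings.
    """

    record_id: str
    sampling_rate: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_minutes(self) -> float:
        return self.n_samples / (self.sampling_rate * 60.0)


@dataclass
class MinuteLabels:
    """Per-minute apnea annotations: True = apnea/hypopnea present in that minute."""

    record_id: str
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)

    @property
    def n_segments(self) -> int:
        return int(self.labels.size)


# ---------------------------------------------------------------------------
# WFDB header/signal dialect (format 16)
# ---------------------------------------------------------------------------

def _parse_gain_token(token: str) -> tuple[float, int]:
    """Parse a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline)."""
    units_split = token.split("/", 1)[0]
    if "(" in units_split:
        gain_s, rest = units_split.split("(", 1)
        baseline = int(rest.rstrip(")"))
    else:
        gain_s, baseline = units_split, 0
    gain = float(gain_s) if gain_s else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline


def read_wfdb_record(path: str | os.PathLike) -> ECGRecord:
    """Read channel 0 of a WFDB header/signal pair as an :class:`ECGRecord`.

    ``path`` may point at the ``.hea`` file or be the record path without
    extension.  Only format-16 signals are supported.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_id = head[0]
    n_sig = int(head[1])
    if n_sig < 1:
        raise ValueError(f"{hea}: record declares zero signal channels")
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"{hea}: header declares {n_sig} signals but lists {len(sig_lines)}")
    tokens = sig_lines[0].split()
    dat_name, fmt = tokens[0], tokens[1]
    if not fmt.startswith("16"):
        raise ValueError(f"{hea}: unsupported signal format '{fmt}' (only format 16)")
    gain, baseline = _parse_gain_token(tokens[2]) if len(tokens) > 2 else (200.0, 0)
    dat = hea.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_sig > 1:
        raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    if n_samples:
        if raw.size < n_samples:
            raise ValueError(f"{dat}: expected {n_samples} samples, found {raw.size}")
        raw = raw[:n_samples]
    samples = (raw.astype(float) - baseline) / gain
    return ECGRecord(record_id=record_id, sampling_rate=fs, samples=samples)


def write_wfdb_record(
    record: ECGRecord, directory: str | os.PathLike, gain: float = 200.0
) -> Path:
    """Serialize a record as a WFDB format-16 header/signal pair.

    Samples are quantized to ``round(x * gain)`` 16-bit integers; the
    quantization step is ``1/gain`` physical units.  Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digital = np.clip(np.rint(record.samples * gain), -32768, 32767).astype("<i2")
    hea = directory / f"{record.record_id}.hea"
    dat_name = f"{record.record_id}.dat"
    fs = record.sampling_rate
    fs_s = f"{int(fs)}" if float(fs).is_integer() else f"{fs}"
    first = int(digital[0]) if digital.size else 0
    checksum = int(np.sum(digital.astype(np.int64)) & 0xFFFF)
    hea.write_text(
        f"{record.record_id} 1 {fs_s} {record.n_samples}\n"
        f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 ECG\n"
    )
    digital.tofile(directory / dat_name)
    return hea


# ---------------------------------------------------------------------------
# CSV signal dialect
# ---------------------------------------------------------------------------

def read_csv_signal(path: str | os.PathLike, sampling_rate: float) -> ECGRecord:
    """Read a one-sample-per-line signal file (optional single header line)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    values: list[float] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if i == 1:  # tolerate a header line
                    continue
                raise ValueError(f"{path}:{i}: non-numeric sample {text!r}") from None
    if not values:
        raise ValueError(f"{path}: empty signal file")
    return ECGRecord(record_id=path.stem, sampling_rate=sampling_rate, samples=np.array(values))


def write_csv_signal(record: ECGRecord, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    return path


# ---------------------------------------------------------------------------
# Per-minute annotations
# ---------------------------------------------------------------------------

_ANN_NORMAL = 1   # MIT code for 'N'
_ANN_APNEA = 8    # MIT code used for the per-minute 'A' apnea mark

_TEXT_SYMBOLS = {"A": True, "1": True, "N": False, "0": False}


def _read_mit_annotations(path: Path) -> list[int]:
    """Decode an MIT-format annotation stream into a list of annotation codes."""
    data = path.read_bytes()
    codes: list[int] = []
    i = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == 59:  # SKIP: 4-byte interval operand follows
            i += 4
        elif code == 63:  # AUX: `interval` bytes of text, padded to even length
            i += interval + (interval & 1)
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        else:
            codes.append(code)
    return codes


def read_minute_annotations(path: str | os.PathLike) -> MinuteLabels:
    """Read per-minute apnea labels from an MIT binary or plain-text file.

    Binary files must carry one annotation per minute with codes 1 ('N') or
    8 ('A'); text files one of ``A``/``N``/``1``/``0`` per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    data = path.read_bytes()
    is_binary = any(b > 0x7F or (b < 0x20 and b not in (0x09, 0x0A, 0x0D)) for b in data)
    record_id = path.stem
    if is_binary or path.suffix == ".apn":
        labels = []
        for code in _read_mit_annotations(path):
            if code == _ANN_APNEA:
                labels.append(True)
            elif code == _ANN_NORMAL:
                labels.append(False)
            else:
                raise ValueError(f"{path}: unexpected annotation code {code}")
        return MinuteLabels(record_id=record_id, labels=np.array(labels, dtype=bool))
    labels = []
    for i, line in enumerate(data.decode().splitlines(), start=1):
        sym = line.strip()
        if not sym:
            continue
        if sym not in _TEXT_SYMBOLS:
            raise ValueError(f"{path}:{i}: unknown annotation symbol {sym!r}")
        labels.append(_TEXT_SYMBOLS[sym])
    return MinuteLabels(record_id=record_id, labels=np.array(labels, dtype=bool))


def write_minute_annotations(
    labels: MinuteLabels,
    path: str | os.PathLike,
    dialect: str = "text",
    sampling_rate: float = 100.0,
) -> Path:
    """Write per-minute labels in the ``text`` or binary ``mit`` dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "text":
        path.write_text("".join("A\n" if v else "N\n" for v in labels.labels))
        return path
    if dialect != "mit":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    minute_samples = int(round(60 * sampling_rate))
    out = bytearray()
    prev = 0
    for m, v in enumerate(np.asarray(labels.labels, dtype=bool)):
        t = m * minute_samples
        delta = t - prev
        prev = t
        code = _ANN_APNEA if v else _ANN_NORMAL
        if delta > 0x3FF:
            out += struct.pack("<H", (59 << 10))
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))
    return path


def check_annotation_consistency(record: ECGRecord, labels: MinuteLabels) -> int:
    """Validate that the annotation count matches the signal duration.

    Returns the number of usable whole minutes (annotations may omit one
    trailing partial minute).  Discrepancies larger than one minute are
    rejected rather than silently truncated.
    """
    whole_minutes = int(np.floor(record.duration_minutes))
    if abs(labels.n_segments - whole_minutes) > 1:
        raise ValueError(
            f"record {record.record_id}: {labels.n_segments} annotated minutes vs "
            f"{whole_minutes} whole minutes of signal (difference exceeds 1)"
        )
    return min(labels.n_segments, whole_minutes + 1)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

META_COLUMNS = ["record_id", "minute_index", "label"]


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a per-segment (or windowed) feature table as delimited text.

    The table must carry the ``record_id``, ``minute_index`` and ``label``
    metadata columns.  Floats are written with full precision so reading the
    table back reproduces the values exactly.
    """
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing required columns: {missing}")
    return table
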