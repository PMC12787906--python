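"""Reading and writing WFDB records and MIT-format beat annotations.

Supports the artifacts the MIT-BIH Arrhythmia Database and the MIT-BIH
Noise Stress Test Database are distributed in: ``.hea`` header files,
``.dat`` signal files in format 212 (two 12-bit two's-complement samples
packed into 3 bytes) or format 16 (little-endian int16), and ``.atr``
annotation files in the interval-coded MIT byte format.

A plain-text CSV dialect is accepted everywhere a WFDB path is, selected
by the ``.csv`` extension, so test fixtures never require binary files:

* records: optional ``# fs=<Hz> record_id=<id>`` comment line, then a
  ``sample_index,value_mV`` header and rows;
* annotations: ``sample_index,code`` header and rows.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EcgRecord",
    "BeatAnnotations",
    "WfdbParseError",
    "UnsupportedFormatError",
    "BEAT_CODES",
    "read_record",
    "read_annotations",
    "filter_beat_annotations",
    "write_record",
    "write_annotations_csv",
]


class WfdbParseError(ValueError):
    """Malformed WFDB header, signal or annotation content."""


class UnsupportedFormatError(WfdbParseError):
    """Signal stored in a WFDB format other than 212 or 16."""


@dataclass(frozen=True)
class EcgRecord:
    """One channel of uniformly sampled ECG in physical units (mV)."""

    record_id: str
    fs: float
    samples: np.ndarray
    channel_index: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, record_id: str | None = None) -> "EcgRecord":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       record_id=self.record_id if record_id is None else record_id)


@dataclass(frozen=True)
class BeatAnnotations:
    """Ordered reference beat labels: (sample_index, annotation code) pairs."""

    record_id: str
    entries: tuple[tuple[int, str], ...]
    beat_only: bool = False

    def __post_init__(self) -> None:
        entries = tuple((int(i), str(c)) for i, c in self.entries)
        object.__setattr__(self, "entries", entries)
        idx = [i for i, _ in entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation sample indices must be strictly increasing")
        if idx and idx[0] < 0:
            raise ValueError("annotation sample indices must be non-negative")

    @property
    def sample_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.entries], dtype=np.int64)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# Standard WFDB annotation code table (index = code stored in .atr files).
_CODE_SYMBOLS: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_CODES = {v: k for k, v in _CODE_SYMBOLS.items()}

#: Annotation symbols that mark a beat (as opposed to rhythm changes,
#: noise markers, waveform boundaries etc.).
BEAT_CODES = frozenset("NLRBAaJSVrFejnE/fQ?")

# Extended pseudo-annotation codes in the .atr byte stream.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# ---------------------------------------------------------------------------
# header + signal reading

def _parse_gain_field(token: str, line_no: int, path: Path) -> tuple[float, int | None, str]:
    """Parse a header gain token like ``200``, ``200(1024)/mV``."""
    units = "mV"
    if "/" in token:
        token, units = token.split("/", 1)
    baseline: int | None = None
    if "(" in token:
        if not token.endswith(")"):
            raise WfdbParseError(f"{path}, line {line_no}: malformed gain field {token!r}")
        token, base = token[:-1].split("(", 1)
        baseline = int(base)
    try:
        gain = float(token)
    except ValueError as exc:
        raise WfdbParseError(f"{path}, line {line_no}: bad gain {token!r}") from exc
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline, units


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int


def _parse_header(header_path: Path) -> tuple[str, float, int, list[_SignalSpec]]:
    try:
        lines = header_path.read_text().splitlines()
    except OSError as exc:
        raise WfdbParseError(f"cannot read header {header_path}: {exc}") from exc
    body = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not body:
        raise WfdbParseError(f"{header_path}, line 1: empty header")
    head = body[0].split()
    if len(head) < 4:
        raise WfdbParseError(
            f"{header_path}, line 1: expected 'name n_sig fs n_samples', got {body[0]!r}")
    record_id = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samples = int(head[3])
    except ValueError as exc:
        raise WfdbParseError(f"{header_path}, line 1: {exc}") from exc
    if len(body) - 1 < n_sig:
        raise WfdbParseError(
            f"{header_path}: header declares {n_sig} signals but has {len(body) - 1} signal lines")
    specs: list[_SignalSpec] = []
    for k in range(n_sig):
        line_no = k + 2
        fields = body[1 + k].split()
        if len(fields) < 3:
            raise WfdbParseError(
                f"{header_path}, line {line_no}: expected 'file format gain ...', got {body[1 + k]!r}")
        fmt_token = fields[1].split("x")[0].split(":")[0].split("+")[0]
        try:
            fmt = int(fmt_token)
        except ValueError as exc:
            raise WfdbParseError(
                f"{header_path}, line {line_no}: bad format {fields[1]!r}") from exc
        gain, baseline, _units = _parse_gain_field(fields[2], line_no, header_path)
        adc_zero = int(fields[4]) if len(fields) > 4 else 0
        specs.append(_SignalSpec(
            file_name=fields[0], fmt=fmt, gain=gain,
            baseline=baseline if baseline is not None else adc_zero))
    return record_id, fs, n_samples, specs


def _decode_fmt212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack 12-bit two's-complement sample pairs from 3-byte groups."""
    n_groups = (n_values + 1) // 2
    if len(raw) < 3 * n_groups:
        raise WfdbParseError(
            f"format-212 stream truncated: need {3 * n_groups} bytes for "
            f"{n_values} samples, got {len(raw)}")
    b = np.frombuffer(raw[: 3 * n_groups], dtype=np.uint8).reshape(-1, 3).astype(np.int64)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_groups, dtype=np.int64)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096  # sign-extend 12-bit
    return out[:n_values]


def _encode_fmt212(adc: np.ndarray) -> bytes:
    vals = np.asarray(adc, dtype=np.int64)
    if vals.size % 2:
        vals = np.concatenate([vals, [0]])
    u = np.where(vals < 0, vals + 4096, vals).astype(np.uint16)
    first, second = u[0::2], u[1::2]
    out = np.empty((first.size, 3), dtype=np.uint8)
    out[:, 0] = first & 0xFF
    out[:, 1] = ((second >> 8) << 4) | (first >> 8)
    out[:, 2] = second & 0xFF
    return out.tobytes()


def read_record(header_path: str | Path, channel: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record (or a CSV fixture) in mV.

    ``channel`` defaults to 0, the upper channel of a two-channel MIT-BIH
    record. Raises :class:`UnsupportedFormatError` for storage formats other
    than 212 and 16 — never a silent misread.
    """
    header_path = Path(header_path)
    if header_path.suffix.lower() == ".csv":
        return _read_record_csv(header_path, channel)
    record_id, fs, n_samples, specs = _parse_header(header_path)
    if not 0 <= channel < len(specs):
        raise ValueError(f"channel {channel} out of range: record has {len(specs)} channels")
    spec = specs[channel]
    if spec.fmt not in (212, 16):
        raise UnsupportedFormatError(
            f"{header_path}: signal format {spec.fmt} not supported (only 212 and 16)")
    sig_path = header_path.parent / spec.file_name
    if not sig_path.exists():
        raise WfdbParseError(f"signal file {sig_path} named by {header_path} does not exist")
    raw = sig_path.read_bytes()
    n_sig_in_file = sum(1 for s in specs if s.file_name == spec.file_name)
    n_values = n_sig_in_file * n_samples
    if spec.fmt == 212:
        flat = _decode_fmt212(raw, n_values)
    else:
        if len(raw) < 2 * n_values:
            raise WfdbParseError(
                f"format-16 stream truncated: need {n_values} samples, "
                f"got {len(raw) // 2}")
        flat = np.frombuffer(raw, dtype="<i2", count=n_values).astype(np.int64)
    # channels sharing a file are interleaved frame by frame
    offset = sum(1 for s in specs[:channel] if s.file_name == spec.file_name)
    adc = flat[offset::n_sig_in_file][:n_samples]
    physical = (adc - spec.baseline) / spec.gain
    return EcgRecord(record_id=record_id, fs=fs, samples=physical, channel_index=channel)


def _read_record_csv(path: Path, channel: int) -> EcgRecord:
    fs = None
    record_id = path.stem
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].replace(",", " ").split():
                    if token.startswith("fs="):
                        fs = float(token[3:])
                    elif token.startswith("record_id="):
                        record_id = token[10:]
                continue
            if line.lower().startswith("sample_index"):
                continue
            parts = line.split(",")
            values.append(float(parts[1]))
    if fs is None:
        raise WfdbParseError(f"{path}: CSV record missing '# fs=<Hz>' comment line")
    if channel != 0:
        raise ValueError("CSV records are single-channel; channel must be 0")
    return EcgRecord(record_id=record_id, fs=fs, samples=np.array(values), channel_index=0)


# ---------------------------------------------------------------------------
# record writing

def write_record(rec: EcgRecord, path: str | Path, gain: float = 200.0,
                 baseline: int = 0) -> Path:
    """Persist a record as WFDB header + format-212 signal, or as CSV.

    Round-trips through :func:`read_record` within one ADC quantum
    (1/gain mV). A ``.csv`` path selects the plain-text dialect instead.
    """
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("refusing to write a zero-length record")
    if path.suffix.lower() == ".csv":
        return _write_record_csv(rec, path)
    if path.suffix.lower() != ".hea":
        path = path.with_suffix(".hea")
    adc = np.rint(rec.samples * gain + baseline).astype(np.int64)
    bad = np.flatnonzero((adc < -2048) | (adc > 2047))
    if bad.size:
        raise ValueError(
            f"sample {bad[0]} (value {rec.samples[bad[0]]} mV) exceeds the 12-bit "
            f"ADC range at gain {gain}")
    name = path.stem
    dat_name = name + ".dat"
    header = (
        f"{name} 1 {rec.fs:g} {rec.n_samples}\n"
        f"{dat_name} 212 {gain:g}({baseline})/mV 12 {baseline} "
        f"{adc[0]} 0 0 ECG\n"
    )
    path.write_text(header)
    (path.parent / dat_name).write_bytes(_encode_fmt212(adc))
    return path


def _write_record_csv(rec: EcgRecord, path: Path) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g} record_id={rec.record_id}\n")
        fh.write("sample_index,value_mV\n")
        for i, v in enumerate(rec.samples):
            fh.write(f"{i},{v:.9g}\n")
    return path


# ---------------------------------------------------------------------------
# annotations

def read_annotations(annotation_path: str | Path) -> BeatAnnotations:
    """Parse a MIT-format ``.atr`` annotation stream (or a CSV fixture).

    Entries come back ordered by sample index with codes verbatim;
    ``beat_only`` is False. Truncated streams and unknown extended codes
    raise :class:`WfdbParseError` naming the byte offset.
    """
    annotation_path = Path(annotation_path)
    if annotation_path.suffix.lower() == ".csv":
        return _read_annotations_csv(annotation_path)
    raw = annotation_path.read_bytes()
    entries: list[tuple[int, str]] = []
    time = 0
    pos = 0

    def next_word() -> int:
        nonlocal pos
        if pos + 2 > len(raw):
            raise WfdbParseError(
                f"{annotation_path}: annotation stream truncated at byte {pos}")
        (w,) = struct.unpack_from("<H", raw, pos)
        pos += 2
        return w

    while pos < len(raw):
        at = pos
        word = next_word()
        code, interval = word >> 10, word & 0x3FF
        if code == 0:
            if interval == 0:
                break  # end of stream
            time += interval  # NOTQRS with a non-zero interval: pure time skip
        elif code in _CODE_SYMBOLS:
            time += interval
            entries.append((time, _CODE_SYMBOLS[code]))
        elif code == _SKIP:
            hi, lo = next_word(), next_word()
            time += (hi << 16) | lo
        elif code in (_NUM, _SUB, _CHN):
            pass  # modifies num/subtype/chan of the previous annotation
        elif code == _AUX:
            pos += interval + (interval & 1)  # aux string, padded to even length
            if pos > len(raw):
                raise WfdbParseError(
                    f"{annotation_path}: aux string at byte {at} overruns the stream")
        else:
            raise WfdbParseError(
                f"{annotation_path}: unknown annotation code {code} at byte {at}")
    entries.sort(key=lambda e: e[0])
    return BeatAnnotations(record_id=annotation_path.stem, entries=tuple(entries),
                           beat_only=False)


def _encode_annotations(entries: Sequence[tuple[int, str]]) -> bytes:
    """Re-encode (sample, code) entries in the simple interval format.

    Inverse of :func:`read_annotations` for streams that use only plain
    interval words (intervals < 1024) — used to verify losslessness.
    """
    out = bytearray()
    prev = 0
    for sample, symbol in entries:
        interval = sample - prev
        if symbol not in _SYMBOL_CODES:
            raise ValueError(f"no MIT code for symbol {symbol!r}")
        if not 0 <= interval < 1024:
            raise ValueError(f"interval {interval} needs SKIP encoding")
        out += struct.pack("<H", (_SYMBOL_CODES[symbol] << 10) | interval)
        prev = sample
    out += struct.pack("<H", 0)
    return bytes(out)


def _read_annotations_csv(path: Path) -> BeatAnnotations:
    entries: list[tuple[int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("sample_index"):
                continue
            idx, code = line.split(",")[:2]
            entries.append((int(idx), code.strip()))
    entries.sort(key=lambda e: e[0])
    return BeatAnnotations(record_id=path.stem, entries=tuple(entries), beat_only=False)


def write_annotations_csv(ann: BeatAnnotations, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_index,code\n")
        for idx, code in ann.entries:
            fh.write(f"{idx},{code}\n")
    return path


def filter_beat_annotations(ann: BeatAnnotations) -> BeatAnnotations:
    """Keep only beat labels (drop rhythm changes, noise markers, etc.).

    The retained set is the standard WFDB beat-code alphabet; idempotent.
    """
    kept = tuple((i, c) for i, c in ann.entries if c in BEAT_CODES)
    return BeatAnnotations(record_id=ann.record_id, entries=kept, beat_only=True)
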