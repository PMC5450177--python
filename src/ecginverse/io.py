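"""Record readers and writers: signal CSV and WFDB format 212.

The CSV dialect is comma-separated, UTF-8, "." decimal, with a required
header row (``time_s,voltage_mv``) and the sampling frequency carried in
a ``# fs_hz=<value>`` comment line.  WFDB support is a minimal format-212
codec (12-bit two's-complement samples packed two-per-three-bytes) for
one- or two-channel records; other WFDB formats are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RecordHandle",
    "read_record",
    "write_record",
    "read_record_csv",
    "write_record_csv",
    "read_record_wfdb",
    "write_record_wfdb",
    "write_annotations_csv",
    "read_annotations_csv",
]


@dataclass(frozen=True)
class RecordHandle:
    """An in-memory single-lead record: samples (mV), rate, provenance."""

    signal: np.ndarray
    fs: float
    lead_name: str = "I"
    source: str = "memory"

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal must be finite-valued")
        object.__setattr__(self, "signal", sig)


def write_record_csv(record: RecordHandle, path) -> None:
    path = Path(path)
    t = np.arange(len(record.signal)) / record.fs
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={record.fs}\n")
        fh.write(f"# lead={record.lead_name}\n")
        fh.write("time_s,voltage_mv\n")
        for ti, vi in zip(t, record.signal):
            fh.write(f"{ti:.6f},{vi:.6f}\n")


def read_record_csv(path) -> RecordHandle:
    path = Path(path)
    fs = None
    lead = "I"
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                if key.strip() == "fs_hz":
                    fs = float(value)
                elif key.strip() == "lead":
                    lead = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "time_s" not in df.columns or "voltage_mv" not in df.columns:
        raise ValueError(f"{path}: malformed header (need time_s,voltage_mv)")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotone time column")
    if fs is None:
        if len(t) > 1:
            raise ValueError(
                f"{path}: missing '# fs_hz=' metadata; refusing to guess"
            )
        raise ValueError(f"{path}: missing '# fs_hz=' metadata")
    return RecordHandle(
        signal=df["voltage_mv"].to_numpy(dtype=float),
        fs=fs,
        lead_name=lead,
        source=f"{path}:csv",
    )


_WFDB_GAIN = 200.0  # ADC units per mV
_WFDB_ADC_MAX = 2047
_WFDB_ADC_MIN = -2048


def write_record_wfdb(record: RecordHandle, path) -> None:
    """Write a single-channel WFDB format-212 record (<path>.hea/.dat)."""
    path = Path(path)
    name = path.name
    adc = np.clip(
        np.round(record.signal * _WFDB_GAIN), _WFDB_ADC_MIN, _WFDB_ADC_MAX
    ).astype(np.int32)
    n = len(adc)
    # pad to an even count for 2-samples-per-3-bytes packing
    padded = np.concatenate([adc, [0]]) if n % 2 else adc
    lo = padded & 0xFFF
    a, b = lo[0::2], lo[1::2]
    packed = np.empty(3 * len(a), dtype=np.uint8)
    packed[0::3] = a & 0xFF
    packed[1::3] = ((a >> 8) & 0x0F) | ((b >> 8) & 0x0F) << 4
    packed[2::3] = b & 0xFF
    with open(path.with_suffix(".dat"), "wb") as fh:
        fh.write(packed.tobytes())
    fs_text = f"{record.fs:g}"
    with open(path.with_suffix(".hea"), "w", encoding="utf-8") as fh:
        fh.write(f"{name} 1 {fs_text} {n}\n")
        fh.write(
            f"{name}.dat 212 {_WFDB_GAIN:g}(0)/mV 12 0 "
            f"{int(adc[0])} 0 0 {record.lead_name}\n"
        )


def read_record_wfdb(path) -> RecordHandle:
    """Read a WFDB format-212 record; returns the first channel in mV."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    with open(hea, encoding="utf-8") as fh:
        lines = [
            ln.strip() for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"{hea}: malformed record line")
    n_sig = int(head[1])
    fs = float(head[2])
    n_samples = int(head[3])
    if n_sig not in (1, 2):
        raise ValueError(f"{hea}: only 1- or 2-channel records supported")
    sig_line = lines[1].split()
    dat_name, fmt = sig_line[0], sig_line[1]
    if fmt.split("x")[0] != "212":
        raise ValueError(f"{hea}: unsupported WFDB format code {fmt!r}")
    gain_field = sig_line[2] if len(sig_line) > 2 else "200"
    gain = float(gain_field.split("(")[0].split("/")[0]) or _WFDB_GAIN
    baseline = 0.0
    if "(" in gain_field:
        baseline = float(gain_field.split("(")[1].split(")")[0])
    raw = np.frombuffer((path.parent / dat_name).read_bytes(), dtype=np.uint8)
    raw = raw[: 3 * (len(raw) // 3)]
    b0, b1, b2 = raw[0::3].astype(np.int32), raw[1::3].astype(np.int32), raw[2::3].astype(np.int32)
    first = b0 | ((b1 & 0x0F) << 8)
    second = b2 | ((b1 & 0xF0) << 4)
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    samples = np.empty(first.size + second.size, dtype=np.int32)
    samples[0::2], samples[1::2] = first, second
    total = n_samples * n_sig
    samples = samples[:total]
    channel0 = samples[::n_sig][:n_samples]
    lead = sig_line[-1] if len(sig_line) > 3 else "I"
    return RecordHandle(
        signal=(channel0 - baseline) / gain,
        fs=fs,
        lead_name=lead,
        source=f"{path}:wfdb212",
    )


def read_record(path, format: str | None = None) -> RecordHandle:
    """Read a record, dispatching on ``format`` or the file extension."""
    path = Path(path)
    fmt = format or ("wfdb" if path.suffix in ("", ".hea", ".dat") else "csv")
    if fmt == "csv":
        return read_record_csv(path)
    if fmt == "wfdb":
        return read_record_wfdb(path.with_suffix(""))
    raise ValueError(f"unknown record format {fmt!r}")


def write_record(record: RecordHandle, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("wfdb" if path.suffix in ("", ".hea", ".dat") else "csv")
    if fmt == "csv":
        write_record_csv(record, path)
    elif fmt == "wfdb":
        write_record_wfdb(record, path.with_suffix(""))
    else:
        raise ValueError(f"unknown record format {fmt!r}")


def write_annotations_csv(annotations, path) -> None:
    rows = [
        {
            "beat_index": a.beat_index,
            "r_time_s": a.r_time,
            "t_time_s": a.t_time,
            "true_k": a.true_params.k if a.true_params else None,
            "true_h_r": a.true_params.h_r if a.true_params else None,
            "true_h_l": a.true_params.h_l if a.true_params else None,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_json(result, label: str, flags: list[str], path) -> None:
    payload = {
        "k": result.k,
        "h_R": result.h_r,
        "h_L": result.h_l,
        "label": label,
        "advisory_flags": flags,
        "rounds_used": result.rounds_used,
        "converged": result.converged,
        "residual_norm": result.residual_norm,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
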