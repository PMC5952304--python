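"""Readers and writers for EEG traces, event annotations and scenario
configurations.

Two trace formats are supported:

* **EDF** (European Data Format): 16-bit integer records, one data
  record per second, physical dimension µV (mV and V are converted on
  read).  Round-trips are lossless up to the 16-bit quantization of the
  stated physical range.
* **CSV**: a single column of µV values with a JSON sidecar
  (``<path>.json``) holding the sampling rate — trivially diffable
  fixtures.

Annotations are CSV tables with columns ``kind, onset_s, offset_s,
attributes`` (attributes as a JSON object).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Annotation, AnnotationSet, EEGRecord
from .simulate import SimConfig

logger = logging.getLogger(__name__)

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1000.0, "V": 1_000_000.0}


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(record: EEGRecord, path) -> None:
    """Write a single-channel EDF file with 1-s data records.

    The recording must span a whole number of seconds (EDF data records
    here are one second each); the physical range is the symmetric
    range covering the trace, digitized to 16 bits.
    """
    fs = record.sampling_rate
    spr = fs
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(spr))
    n_records, rem = divmod(record.n_samples, spr)
    if rem:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"(got {record.n_samples} samples at {spr} Hz)"
        )
    peak = float(np.max(np.abs(record.samples))) or 1.0
    # the header stores the range as 8 ASCII chars; digitize against the
    # header-rounded value so reader and writer use the same scale (the
    # tiny inflation keeps the rounded range covering the peak)
    phys_str = f"{peak * 1.0001:.5g}"
    if len(phys_str) > 7:
        phys_str = f"{peak * 1.001:.3g}"
    phys_max = float(phys_str)
    # inverse of the EDF mapping phys = (dig - dig_min) * scale + phys_min
    scale = (2.0 * phys_max) / 65535.0
    digital = np.clip(np.rint((record.samples + phys_max) / scale) - 32768,
                      -32768, 32767).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("synthetic rodent", 80),
        _pad("ictal package", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 + 256), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad("1", 4),
    ])
    sig = b"".join([
        _pad(record.channel_label[:16], 16),
        _pad("screw electrode", 80),
        _pad("uV", 8),
        _pad("-" + phys_str, 8),
        _pad(phys_str, 8),
        _pad("-32768", 8),
        _pad("32767", 8),
        _pad("", 80),
        _pad(str(spr), 8),
        _pad("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(digital.tobytes())


def read_edf(path) -> EEGRecord:
    """Read the first channel of an EDF file, converting to µV."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_duration = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header") from exc
        if ns < 1 or record_duration <= 0 or n_records < 0:
            raise ValueError(f"{path}: malformed EDF header")
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise ValueError(f"{path}: truncated EDF signal headers")

        def fld(block: int, width: int, index: int) -> str:
            # per-signal header fields are stored grouped by field
            start = sum(w * ns for w in _EDF_FIELD_WIDTHS[:block]) \
                + index * width
            return sig_head[start:start + width].decode("ascii").strip()

        label = fld(0, 16, 0)
        unit = fld(2, 8, 0)
        if unit not in _UNIT_TO_UV:
            raise ValueError(
                f"{path}: unknown physical dimension {unit!r}; expected "
                f"one of {sorted(_UNIT_TO_UV)}"
            )
        phys_min = float(fld(3, 8, 0))
        phys_max = float(fld(4, 8, 0))
        dig_min = float(fld(5, 8, 0))
        dig_max = float(fld(6, 8, 0))
        if phys_max <= phys_min or dig_max <= dig_min:
            raise ValueError(f"{path}: invalid physical/digital ranges")
        spr = [int(fld(8, 8, i)) for i in range(ns)]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_record = sum(spr)
    if raw.size < n_records * per_record:
        raise ValueError(f"{path}: data area shorter than header declares")
    raw = raw[:n_records * per_record].reshape(n_records, per_record)
    chan = raw[:, :spr[0]].reshape(-1).astype(np.float64)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    phys = (chan - dig_min) * scale + phys_min
    rate = spr[0] / record_duration
    return EEGRecord(phys * _UNIT_TO_UV[unit], rate, channel_label=label)


#: Widths of the grouped per-signal EDF header fields, in order: label,
#: transducer, physical dimension, physical min/max, digital min/max,
#: prefiltering, samples per record, reserved.
_EDF_FIELD_WIDTHS = (16, 80, 8, 8, 8, 8, 8, 80, 8, 32)


def write_csv_trace(record: EEGRecord, path) -> None:
    """One µV value per line plus a JSON sidecar with the rate."""
    path = Path(path)
    np.savetxt(path, record.samples, fmt="%.6f")
    sidecar = {
        "sampling_rate": record.sampling_rate,
        "start_time": record.start_time,
        "channel_label": record.channel_label,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_csv_trace(path, sampling_rate: float | None = None) -> EEGRecord:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    start_time, label = 0.0, "EEG"
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        sampling_rate = sidecar["sampling_rate"]
        start_time = sidecar.get("start_time", 0.0)
        label = sidecar.get("channel_label", "EEG")
    elif sampling_rate is None:
        raise ValueError(
            f"{path}: no JSON sidecar found and no sampling rate given"
        )
    samples = np.loadtxt(path, dtype=np.float64, ndmin=1)
    return EEGRecord(samples, sampling_rate, start_time, label)


def read_eeg(path, format: str | None = None,
             sampling_rate: float | None = None) -> EEGRecord:
    """Read a trace from ``path``; format inferred from the suffix when
    not given (``edf`` or ``csv``)."""
    if format is None:
        format = Path(path).suffix.lstrip(".").lower()
    if format == "edf":
        return read_edf(path)
    if format == "csv":
        return read_csv_trace(path, sampling_rate)
    raise ValueError(f"unknown EEG format {format!r}; expected edf or csv")


def write_eeg(record: EEGRecord, path, format: str | None = None) -> None:
    if format is None:
        format = Path(path).suffix.lstrip(".").lower()
    if format == "edf":
        write_edf(record, path)
    elif format == "csv":
        write_csv_trace(record, path)
    else:
        raise ValueError(f"unknown EEG format {format!r}; expected edf or csv")


def write_annotations(annotations: AnnotationSet, path) -> None:
    frame = pd.DataFrame([
        {
            "kind": e.kind,
            "onset_s": e.onset,
            "offset_s": e.offset,
            "attributes": json.dumps(e.attributes, sort_keys=True),
        }
        for e in annotations
    ], columns=["kind", "onset_s", "offset_s", "attributes"])
    frame.to_csv(path, index=False)


def read_annotations(path) -> AnnotationSet:
    frame = pd.read_csv(path, dtype={"kind": str})
    events = []
    for row in frame.itertuples(index=False):
        attrs = {}
        if isinstance(row.attributes, str) and row.attributes.strip():
            attrs = json.loads(row.attributes)
        events.append(Annotation(row.kind, float(row.onset_s),
                                 float(row.offset_s), attrs))
    annotations = AnnotationSet(events)
    overlaps = annotations.overlapping_pairs("seizure")
    if overlaps:
        logger.warning("read_annotations: %d overlapping seizure row pairs "
                       "in %s", len(overlaps), path)
    return annotations


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def save_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
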