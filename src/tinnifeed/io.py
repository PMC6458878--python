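"""Reading and writing EEG recordings and behavioral tables.

Recordings round-trip through the two formats the recording hardware families
use: EDF+ (16-bit, annotations carried in an ``EDF Annotations`` TAL channel)
and the BrainVision triplet (``.vhdr``/``.vmrk`` INI-style text headers plus a
multiplexed IEEE float32 ``.eeg`` binary).  Reading goes through MNE; the
writers are implemented here.

Behavioral tables are tidy CSVs with columns ``subject,timepoint,outcome,value``.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Event, RawRecording


class FormatError(ValueError):
    """Malformed or incomplete recording file(s)."""


# --------------------------------------------------------------------------
# EDF+

_EDF_EPOCH = _dt.datetime(2000, 1, 1, 0, 0, 0)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def _num8(v: float) -> str:
    """Format a physical range bound into <= 8 ascii chars."""
    for fmt in ("%.7g", "%.6g", "%.5g", "%.4g", "%.1e"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise FormatError(f"cannot format {v} in 8 chars")


def write_edf(rec: RawRecording, path: "str | Path") -> Path:
    """Write an EDF+C file with per-channel physical ranges and annotations."""
    path = Path(path)
    srate = rec.srate
    if abs(srate - round(srate)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(srate))  # samples per 1 s record
    n_records = int(np.ceil(rec.n_samples / spr))
    n_sig = rec.n_channels + 1  # + annotations channel

    x = rec.samples
    pmin = x.min(axis=1)
    pmax = x.max(axis=1)
    flat = pmax - pmin < 1e-6
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767

    # digitize
    scale = (pmax - pmin) / (dmax - dmin)
    padded = np.full((rec.n_channels, n_records * spr), np.nan)
    padded[:, : rec.n_samples] = x
    padded[:, rec.n_samples :] = pmin[:, None] + scale[:, None] * (0 - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    # annotations: one TAL block per record
    ann_spr = 60  # 120 bytes per record
    events_by_rec: dict[int, list[Event]] = {}
    for ev in rec.events:
        events_by_rec.setdefault(int(ev.latency // spr), []).append(ev)
    ann_records = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00"
        for ev in events_by_rec.get(r, []):
            onset = ev.latency / srate
            tal += f"+{onset:.4f}\x14{ev.label}\x14\x00"
        b = tal.encode("utf-8")
        if len(b) > 2 * ann_spr:
            raise FormatError("too many events in one EDF record")
        ann_records.append(b.ljust(2 * ann_spr, b"\x00"))

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad(f"Startdate 01-JAN-2000 X X X ref={rec.reference}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("EDF+C", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_sig), 4))

        labels = [f"EEG {n}" for n in rec.channel_names] + ["EDF Annotations"]
        fh.write(b"".join(_pad(lb, 16) for lb in labels))
        fh.write(b"".join(_pad("", 80) for _ in range(n_sig)))
        fh.write(b"".join(_pad("uV", 8) for _ in rec.channel_names) + _pad("", 8))
        for v in pmin:
            fh.write(_pad(_num8(v), 8))
        fh.write(_pad("-1", 8))
        for v in pmax:
            fh.write(_pad(_num8(v), 8))
        fh.write(_pad("1", 8))
        fh.write(b"".join(_pad(str(dmin), 8) for _ in range(n_sig - 1)) + _pad("-32768", 8))
        fh.write(b"".join(_pad(str(dmax), 8) for _ in range(n_sig - 1)) + _pad("32767", 8))
        fh.write(b"".join(_pad("", 80) for _ in range(n_sig)))
        fh.write(b"".join(_pad(str(spr), 8) for _ in range(n_sig - 1)))
        fh.write(_pad(str(ann_spr), 8))
        fh.write(b"".join(_pad("", 32) for _ in range(n_sig)))

        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            fh.write(ann_records[r])
    return path


# --------------------------------------------------------------------------
# BrainVision triplet


def write_brainvision(rec: RawRecording, vhdr_path: "str | Path") -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32, µV)."""
    vhdr_path = Path(vhdr_path)
    if vhdr_path.suffix != ".vhdr":
        raise FormatError("BrainVision header path must end in .vhdr")
    stem = vhdr_path.with_suffix("")
    eeg_path = stem.with_suffix(".eeg")
    vmrk_path = stem.with_suffix(".vmrk")

    sampling_interval_us = 1e6 / rec.srate
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},{rec.reference},1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, ev in enumerate(rec.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,{ev.label},{ev.latency + 1},1,0")
    vmrk_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.samples.astype("<f4").T.tofile(eeg_path)  # multiplexed: time-major
    return vhdr_path


# --------------------------------------------------------------------------
# reading (MNE-backed)


def _events_from_annotations(raw, srate: float) -> list[Event]:
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        label = desc.split("/", 1)[-1]  # "Stimulus/EO_start" -> "EO_start"
        if label.endswith("_start"):
            events.append(Event(latency=int(round(onset * srate)), label=label))
    events.sort(key=lambda e: e.latency)
    return events


def read_recording(path: "str | Path") -> RawRecording:
    """Read an EDF+ file or a BrainVision triplet into a RawRecording."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        reference = "FCz"
        with open(path, "rb") as fh:
            fh.seek(88)
            rid = fh.read(80).decode("ascii", "ignore")
        for tok in rid.split():
            if tok.startswith("ref="):
                reference = tok[4:]
        names = [n.removeprefix("EEG ") for n in raw.ch_names]
    elif path.suffix.lower() == ".vhdr":
        for member in (path, path.with_suffix(".vmrk"), path.with_suffix(".eeg")):
            if not member.exists():
                raise FormatError(f"BrainVision triplet missing member: {member.name}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        names = list(raw.ch_names)
        reference = "FCz"
        for line in path.read_text(encoding="utf-8", errors="ignore").splitlines():
            if line.startswith("Ch1="):
                parts = line.split("=", 1)[1].split(",")
                if len(parts) > 1 and parts[1]:
                    reference = parts[1]
    else:
        raise FormatError(f"unsupported recording format: {path.suffix}")

    srate = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # MNE holds volts
    return RawRecording(
        samples=data_uv,
        srate=srate,
        channel_names=names,
        reference=reference,
        events=_events_from_annotations(raw, srate),
    )


def write_recording(rec: RawRecording, path: "str | Path") -> Path:
    """Write ``rec`` as EDF+ (.edf) or BrainVision (.vhdr) based on suffix."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return write_edf(rec, path)
    if path.suffix.lower() == ".vhdr":
        return write_brainvision(rec, path)
    raise FormatError(f"unsupported recording format: {path.suffix}")


# --------------------------------------------------------------------------
# behavioral tables

BEHAVIOR_COLUMNS = ["subject", "timepoint", "outcome", "value"]


def write_behavior(table: pd.DataFrame, path: "str | Path") -> Path:
    missing = set(BEHAVIOR_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"behavior table missing columns: {sorted(missing)}")
    path = Path(path)
    table[BEHAVIOR_COLUMNS].to_csv(path, index=False)
    return path


def read_behavior(path: "str | Path") -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(BEHAVIOR_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"behavior table missing columns: {sorted(missing)}")
    return table[BEHAVIOR_COLUMNS]
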