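"""File import/export.

Two paths in, one canonical container out:

* BrainVision (.vhdr/.vmrk/.eeg): header-only import.  The text headers are
  parsed and the *original* binary file is linked in place, so a multi-GB
  EEG-fMRI file is imported in milliseconds without duplicating the payload.
* EDF: read-convert path (the record-interleaved layout cannot be linked).
* Internal container: ``<base>.json`` header + ``<base>.bin`` float32
  multiplexed samples.  Header-only edits never rewrite the binary.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import os
import re
import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    ArraySource,
    BinaryFileSource,
    ChannelInfo,
    ChannelKind,
    Event,
    Recording,
    read_window,
)
from .errors import IntegrityError, ParameterError
from .scoring import ScoreSet

logger = logging.getLogger(__name__)

__all__ = [
    "import_brainvision",
    "import_edf",
    "write_internal",
    "read_internal",
]

_INTERNAL_DTYPE = "<f4"


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def _parse_ini(path: Path) -> dict[str, dict[str, str]]:
    """Parse the BrainVision INI dialect: ordered keys, ';' comments."""
    sections: dict[str, dict[str, str]] = {}
    current: Optional[dict[str, str]] = None
    for raw in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, val = line.partition("=")
            current[key.strip()] = val.strip()
    return sections


def _guess_kind(name: str) -> ChannelKind:
    lname = name.lower()
    if "ecg" in lname or "ekg" in lname:
        return ChannelKind.ECG
    if "eog" in lname or lname in {"veog", "heog"}:
        return ChannelKind.EOG
    if "emg" in lname or lname in {"chin", "ment"}:
        return ChannelKind.EMG
    return ChannelKind.EEG


def _parse_bv_timestamp(stamp: str) -> Optional[_dt.datetime]:
    # 20-digit format: YYYYMMDDhhmmssuuuuuu
    if not re.fullmatch(r"\d{20}", stamp or ""):
        return None
    try:
        return _dt.datetime(
            int(stamp[0:4]), int(stamp[4:6]), int(stamp[6:8]),
            int(stamp[8:10]), int(stamp[10:12]), int(stamp[12:14]),
            int(stamp[14:20]),
        )
    except ValueError:
        return None


def import_brainvision(vhdr_path) -> Recording:
    """Import a BrainVision triple by translating headers only.

    The sample payload stays in the vendor's ``.eeg`` file, which is linked
    as the recording's source; INT16 resolution scaling happens on read.
    Markers become :class:`Event` objects (1-based vendor positions are
    converted to 0-based onsets).  A "New Segment" marker timestamp, when
    present and well formed, sets ``start_clock_time``.
    """
    vhdr_path = Path(vhdr_path)
    hdr = _parse_ini(vhdr_path)
    common = hdr.get("Common Infos", {})
    binary = hdr.get("Binary Infos", {})
    chans = hdr.get("Channel Infos", {})

    data_file = vhdr_path.parent / common["DataFile"]
    if not data_file.exists():
        raise IntegrityError(f"data file {data_file} referenced by header not found")
    n_channels = int(common["NumberOfChannels"])
    sampling_interval_us = float(common["SamplingInterval"])
    if sampling_interval_us <= 0:
        raise ParameterError("SamplingInterval must be > 0")
    fs = 1e6 / sampling_interval_us

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise ParameterError(f"unsupported DataOrientation {orientation!r}")
    fmt = binary.get("BinaryFormat", "INT_16").upper()
    if fmt in ("INT_16", "INT16"):
        dtype = "<i2"
    elif fmt in ("IEEE_FLOAT_32", "FLOAT_32", "FLOAT32"):
        dtype = "<f4"
    else:
        raise ParameterError(f"unsupported BinaryFormat {fmt!r}")
    if orientation == "VECTORIZED" and dtype == "<i2":
        logger.warning("VECTORIZED INT16 layout: per-channel reads take the slower path")

    channels: list[ChannelInfo] = []
    resolutions = np.ones(n_channels)
    for i in range(n_channels):
        entry = chans.get(f"Ch{i + 1}", f"Ch{i + 1},,1")
        parts = entry.split(",")
        name = parts[0].replace(r"\1", ",") if parts else f"Ch{i + 1}"
        res = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
        unit = parts[3] if len(parts) > 3 and parts[3] else "µV"
        scale = 1.0
        if unit in ("µV", "uV", "μV"):
            pass
        elif unit == "mV":
            scale = 1e3
        elif unit == "V":
            scale = 1e6
        else:
            logger.warning("channel %s: unknown unit %r, assuming µV", name, unit)
        resolutions[i] = res * scale
        channels.append(ChannelInfo(name=name, kind=_guess_kind(name)))

    events: list[Event] = []
    start_clock_time: Optional[_dt.datetime] = None
    marker_file = common.get("MarkerFile")
    if marker_file:
        vmrk_path = vhdr_path.parent / marker_file
        if vmrk_path.exists():
            markers = _parse_ini(vmrk_path).get("Marker Infos", {})
            for key in sorted(markers, key=lambda k: int(k[2:]) if k[2:].isdigit() else 0):
                parts = markers[key].split(",")
                if len(parts) < 4:
                    continue
                mtype, desc = parts[0], parts[1]
                position = int(parts[2])  # 1-based
                points = int(parts[3]) if parts[3] else 0
                label = desc or mtype
                events.append(
                    Event(label=label, onset=position - 1, duration=points, payload=mtype)
                )
                if mtype == "New Segment" and len(parts) >= 6 and start_clock_time is None:
                    ts = _parse_bv_timestamp(parts[5])
                    if ts is not None:
                        start_clock_time = ts
                    elif parts[5]:
                        logger.warning("malformed New Segment timestamp %r", parts[5])
        else:
            logger.warning("marker file %s missing; importing without events", vmrk_path)

    source = BinaryFileSource(
        data_file,
        n_channels=n_channels,
        dtype=dtype,
        orientation=orientation.lower(),
        resolutions=resolutions,
    )
    rec = Recording(
        sampling_rate=fs,
        channels=channels,
        source=source,
        start_clock_time=start_clock_time,
        events=events,
    )
    rec.log(f"import_brainvision {vhdr_path.name}")
    return rec


# ---------------------------------------------------------------------------
# EDF (read-convert path)
# ---------------------------------------------------------------------------

def import_edf(path) -> Recording:
    """Read a 16-bit EDF file fully into memory and convert to uV.

    EDF interleaves short per-record chunks, so unlike BrainVision the file
    cannot be linked in place; this is a read-convert path intended for
    modest files.  Only a single common sampling rate is supported
    (annotation channels are skipped).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IntegrityError("EDF header truncated")
        start_date = head[168:176].decode("ascii", "replace").strip()
        start_time = head[176:184].decode("ascii", "replace").strip()
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        ns = int(head[252:256])

        def fields(width):
            return [fh.read(width).decode("ascii", "replace").strip() for _ in range(ns)]

        labels = fields(16)
        fields(80)  # transducer
        units = fields(8)
        phys_min = [float(v) for v in fields(8)]
        phys_max = [float(v) for v in fields(8)]
        dig_min = [int(v) for v in fields(8)]
        dig_max = [int(v) for v in fields(8)]
        fields(80)  # prefilter
        nsamp = [int(v) for v in fields(8)]
        fields(32)  # reserved

        keep = [i for i, lab in enumerate(labels) if "annotation" not in lab.lower()]
        rates = {nsamp[i] for i in keep}
        if len(rates) != 1:
            raise ParameterError("EDF with mixed sampling rates not supported")
        spr = rates.pop()
        fs = spr / record_dur

        gains = np.array(
            [(phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i]) for i in keep]
        )
        offsets = np.array(
            [phys_min[i] - gains[k] * dig_min[i] for k, i in enumerate(keep)]
        )
        unit_scale = np.array(
            [1e3 if units[i].lower() == "mv" else 1.0 for i in keep]
        )

        data = np.empty((len(keep), n_records * spr))
        rec_len = sum(nsamp)
        for r in range(n_records):
            raw = np.frombuffer(fh.read(rec_len * 2), dtype="<i2")
            if raw.size < rec_len:
                raise IntegrityError("EDF data truncated")
            pos = 0
            starts = {}
            for i in range(ns):
                starts[i] = pos
                pos += nsamp[i]
            for k, i in enumerate(keep):
                seg = raw[starts[i] : starts[i] + nsamp[i]].astype(np.float64)
                data[k, r * spr : (r + 1) * spr] = (seg * gains[k] + offsets[k]) * unit_scale[k]

    start_clock = None
    try:
        d, m, y = (int(v) for v in start_date.split("."))
        hh, mm, ss = (int(v) for v in start_time.split("."))
        y += 2000 if y < 85 else 1900
        start_clock = _dt.datetime(y, m, d, hh, mm, ss)
    except (ValueError, AttributeError):
        pass

    channels = [ChannelInfo(name=labels[i] or f"Ch{i + 1}", kind=_guess_kind(labels[i]))
                for i in keep]
    rec = Recording(
        sampling_rate=fs,
        channels=channels,
        source=ArraySource(data),
        start_clock_time=start_clock,
    )
    rec.log(f"import_edf {path.name}")
    return rec


# ---------------------------------------------------------------------------
# internal container
# ---------------------------------------------------------------------------

def _scoreset_to_dict(s: ScoreSet) -> dict:
    return {
        "scorer_id": s.scorer_id,
        "window_length_s": s.window_length_s,
        "stages": [int(v) for v in s.stages],
        "artefact_flags": [bool(v) for v in s.artefact_flags],
        "fpl_sample": s.fpl_sample,
        "opl_sample": s.opl_sample,
    }


def _scoreset_from_dict(d: dict) -> ScoreSet:
    return ScoreSet(
        scorer_id=d["scorer_id"],
        window_length_s=d["window_length_s"],
        stages=np.asarray(d["stages"], dtype=np.int64),
        artefact_flags=np.asarray(d["artefact_flags"], dtype=bool),
        fpl_sample=d.get("fpl_sample"),
        opl_sample=d.get("opl_sample"),
    )


def write_internal(rec: Recording, basename, chunk_samples: int = 1 << 16):
    """Write ``<basename>.json`` + ``<basename>.bin`` (float32 multiplexed).

    Samples are streamed through in bounded chunks, honouring the windowed
    access contract even for recordings far larger than memory.
    Returns ``(json_path, bin_path)``.
    """
    base = Path(basename)
    json_path = base.with_suffix(".json")
    bin_path = base.with_suffix(".bin")
    names = rec.channel_names
    # stream through a temp file so overwriting a recording in place never
    # truncates the binary we are still reading from
    tmp_path = bin_path.with_name(bin_path.name + ".tmp")
    with open(tmp_path, "wb") as fh:
        for start in range(0, rec.n_samples, chunk_samples):
            length = min(chunk_samples, rec.n_samples - start)
            block = read_window(rec, names, start, length)
            fh.write(np.ascontiguousarray(block.T, dtype=_INTERNAL_DTYPE).tobytes())
    os.replace(tmp_path, bin_path)
    header = {
        "format": "fastkit-internal",
        "version": 1,
        "sampling_rate": rec.sampling_rate,
        "n_samples": rec.n_samples,
        "start_clock_time": (
            rec.start_clock_time.isoformat(timespec="microseconds")
            if rec.start_clock_time
            else None
        ),
        "binary": {
            "path": bin_path.name,
            "dtype": _INTERNAL_DTYPE,
            "orientation": "multiplexed",
        },
        "channels": [
            {
                "name": c.name,
                "kind": c.kind.value,
                "unit": c.unit,
                "scale_group": c.scale_group,
                "position2d": list(c.position2d) if c.position2d else None,
            }
            for c in rec.channels
        ],
        "events": [
            {
                "label": e.label,
                "onset": int(e.onset),
                "duration": int(e.duration),
                "payload": e.payload if isinstance(e.payload, (str, int, float, type(None))) else str(e.payload),
            }
            for e in rec.events
        ],
        "scores": [_scoreset_to_dict(s) for s in rec.scores],
        "history": list(rec.history),
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=1)
    return json_path, bin_path


def read_internal(basename) -> Recording:
    """Read an internal container back; verifies header/binary consistency."""
    base = Path(basename)
    json_path = base if base.suffix == ".json" else base.with_suffix(".json")
    with open(json_path) as fh:
        header = json.load(fh)
    bin_path = json_path.parent / header["binary"]["path"]
    channels = [
        ChannelInfo(
            name=c["name"],
            kind=ChannelKind(c["kind"]),
            unit=c.get("unit", "uV"),
            scale_group=c.get("scale_group"),
            position2d=tuple(c["position2d"]) if c.get("position2d") else None,
        )
        for c in header["channels"]
    ]
    expected = header["n_samples"] * len(channels) * np.dtype(header["binary"]["dtype"]).itemsize
    actual = os.path.getsize(bin_path)
    if actual != expected:
        raise IntegrityError(
            f"binary payload is {actual} bytes, header implies {expected}"
        )
    source = BinaryFileSource(
        bin_path,
        n_channels=len(channels),
        dtype=header["binary"]["dtype"],
        orientation=header["binary"]["orientation"],
    )
    start = header.get("start_clock_time")
    rec = Recording(
        sampling_rate=header["sampling_rate"],
        channels=channels,
        source=source,
        start_clock_time=_dt.datetime.fromisoformat(start) if start else None,
        events=[
            Event(e["label"], e["onset"], e.get("duration", 0), e.get("payload"))
            for e in header["events"]
        ],
        scores=[_scoreset_from_dict(d) for d in header.get("scores", [])],
        history=list(header.get("history", [])),
    )
    return rec
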