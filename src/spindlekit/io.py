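"""Readers and writers for recordings and event tables.

Supported recording formats:

* ``hdf5`` -- datasets ``/data`` (float64, channels x samples), ``/fs`` (scalar),
  ``/channel_ids``, optional ``/region_labels`` and ``/polar_angle``.
* ``csv``  -- a ``time`` column plus one column per channel; the sampling rate is
  recovered from the time axis.
* ``edf``  -- European Data Format, 16-bit. The writer emits a standard EDF
  header with one-second data records (or a single record when the sampling
  rate is not an integer); samples survive the round trip up to the format's
  16-bit quantization.

Event tables are tab-delimited with columns
``channel  start_s  end_s  score  detector``.
"""
from __future__ import annotations

import datetime as _dt
import os
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .recording import Recording, SpindleEvent, validate_events

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]

_FORMATS = ("hdf5", "csv", "edf")


def _infer_format(path: str, format: Optional[str]) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in _FORMATS:
            raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    table = {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".edf": "edf"}
    if ext not in table:
        raise ParameterError(f"cannot infer format from extension {ext!r}; pass format=")
    return table[ext]


def read_recording(path: str, format: Optional[str] = None) -> Recording:
    """Read a recording from ``path``; ``format`` is inferred from the extension."""
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv":
        return _read_csv(path)
    return _read_edf(path)


def write_recording(rec: Recording, path: str, format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        _write_hdf5(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        _write_edf(rec, path)


# ---------------------------------------------------------------- HDF5 / CSV


def _write_hdf5(rec: Recording, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, dtype="float64")
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("channel_ids", data=np.array(rec.channel_ids, dtype="S"))
        if rec.region_labels is not None:
            f.create_dataset("region_labels", data=np.array(rec.region_labels, dtype="S"))
        if rec.polar_angle is not None:
            f.create_dataset("polar_angle", data=rec.polar_angle)
        for k, v in rec.meta.items():
            f.attrs[str(k)] = str(v)


def _read_hdf5(path: str) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            if "data" not in f or "fs" not in f:
                raise FormatError(f"{path}: missing /data or /fs dataset")
            data = np.asarray(f["data"], dtype=float)
            fs = float(np.asarray(f["fs"]))
            if "channel_ids" in f:
                ids = [x.decode() for x in np.asarray(f["channel_ids"])]
            else:
                ids = [f"ch{i}" for i in range(data.shape[0])]
            labels = (
                [x.decode() for x in np.asarray(f["region_labels"])]
                if "region_labels" in f
                else None
            )
            angle = np.asarray(f["polar_angle"]) if "polar_angle" in f else None
            meta = {k: f.attrs[k] for k in f.attrs}
    except OSError as e:  # not an HDF5 file / truncated
        raise FormatError(f"{path}: not readable as HDF5 ({e})") from e
    return Recording(data, fs, ids, labels, angle, meta)


def _write_csv(rec: Recording, path: str) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for i, ch in enumerate(rec.channel_ids):
        df[ch] = rec.data[i]
    df.to_csv(path, index=False, float_format="%.10g")


def _read_csv(path: str) -> Recording:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise FormatError(f"{path}: not readable as CSV ({e})") from e
    if "time" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: CSV must have a 'time' column plus channel columns")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples to recover fs")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6 * np.median(dt):
        raise FormatError(f"{path}: time axis is not uniformly sampled")
    fs = 1.0 / float(np.median(dt))
    ids = [c for c in df.columns if c != "time"]
    data = df[ids].to_numpy(dtype=float).T
    return Recording(data, fs, ids)


# ----------------------------------------------------------------------- EDF

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: str) -> None:
    fs = rec.fs
    n = rec.n_samples
    if abs(fs - round(fs)) < 1e-9 and n % int(round(fs)) == 0:
        spr = int(round(fs))           # one-second records
        record_dur = 1.0
    else:
        spr = n                        # single record holding everything
        record_dur = n / fs
    n_records = n // spr
    ns = rec.n_channels

    phys_min = np.minimum(rec.data.min(axis=1), -1e-9)
    phys_max = np.maximum(rec.data.max(axis=1), 1e-9)
    header_bytes = 256 * (ns + 1)
    now = _dt.datetime(2000, 1, 1)

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        f.write(_edf_field(now.strftime("%d.%m.%y"), 8))
        f.write(_edf_field(now.strftime("%H.%M.%S"), 8))
        f.write(_edf_field(str(header_bytes), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(str(n_records), 8))
        f.write(_edf_field(f"{record_dur:.6g}", 8))
        f.write(_edf_field(str(ns), 4))
        for ch in rec.channel_ids:
            f.write(_edf_field(ch, 16))
        for _ in range(ns):
            f.write(_edf_field("", 80))          # transducer
        for _ in range(ns):
            f.write(_edf_field("uV", 8))
        for v in phys_min:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for _ in range(ns):
            f.write(_edf_field(str(_EDF_DIG_MIN), 8))
        for _ in range(ns):
            f.write(_edf_field(str(_EDF_DIG_MAX), 8))
        for _ in range(ns):
            f.write(_edf_field("", 80))          # prefiltering
        for _ in range(ns):
            f.write(_edf_field(str(spr), 8))
        for _ in range(ns):
            f.write(_edf_field("", 32))

        # physical -> digital; re-read the textual phys range so the round
        # trip is limited by 16-bit quantization only, not by header rounding
        pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
        gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
        for r in range(n_records):
            for i in range(ns):
                seg = rec.data[i, r * spr : (r + 1) * spr]
                dig = np.round((seg - pmin[i]) * gain[i]) + _EDF_DIG_MIN
                dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
                f.write(dig.tobytes())


def _read_edf(path: str) -> Recording:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: EDF header truncated at byte {len(head)}")
        try:
            header_bytes = int(head[184:192])
            n_records = int(head[236:244])
            record_dur = float(head[244:252])
            ns = int(head[252:256])
        except ValueError as e:
            raise FormatError(f"{path}: malformed EDF fixed header ({e})") from e
        sig_head = f.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise FormatError(
                f"{path}: EDF signal header truncated at byte {256 + len(sig_head)}"
            )

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        # per-signal header blocks: label 16, transducer 80, phys dim 8,
        # phys min 8, phys max 8, dig min 8, dig max 8, prefilter 80, spr 8
        labels = fields(0, 16)
        try:
            pmin = np.array([float(x) for x in fields(104, 8)])
            pmax = np.array([float(x) for x in fields(112, 8)])
            dmin = np.array([float(x) for x in fields(120, 8)])
            dmax = np.array([float(x) for x in fields(128, 8)])
            spr = [int(x) for x in fields(216, 8)]
        except ValueError as e:
            raise FormatError(f"{path}: malformed EDF signal header ({e})") from e

        if len(set(spr)) != 1:
            raise FormatError(f"{path}: channels with different record lengths {set(spr)}")
        spr0 = spr[0]
        payload = f.read()

    expected = n_records * ns * spr0 * 2
    if len(payload) < expected:
        raise FormatError(
            f"{path}: EDF data truncated, record {len(payload) // (ns * spr0 * 2)} incomplete"
        )
    raw = np.frombuffer(payload[:expected], dtype="<i2")
    raw = raw.reshape(n_records, ns, spr0)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (raw.transpose(1, 0, 2).reshape(ns, -1) - dmin[:, None]) * gain[:, None] + pmin[:, None]
    fs = spr0 / record_dur
    return Recording(np.ascontiguousarray(data), fs, labels, meta={"header_bytes": header_bytes})


# -------------------------------------------------------------- event tables

_EVENT_COLUMNS = ["channel", "start_s", "end_s", "score", "detector"]


def write_events(events: Sequence[SpindleEvent], path: str) -> None:
    """Write events as a tab-delimited table; validates the non-overlap invariant."""
    validate_events(events)
    df = pd.DataFrame(
        [(e.channel_id, e.t_start, e.t_end, e.score, e.detector) for e in events],
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events(path: str) -> list[SpindleEvent]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:
        raise FormatError(f"{path}: not readable as an event table ({e})") from e
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing event columns {missing}")
    return [
        SpindleEvent(str(r.channel), float(r.start_s), float(r.end_s), float(r.score), str(r.detector))
        for r in df.itertuples()
    ]
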