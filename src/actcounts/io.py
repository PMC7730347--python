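"""Readers and writers for the package's text formats.

Two raw-acceleration CSV dialects are supported:

* *generic* — column header ``x,y,z`` or ``time,x,y,z``; the sampling rate
  and units come from the caller (or, with a ``time`` column, the rate can
  be inferred from the timestamps);
* *ActiGraph RAW* — the multi-line header emitted by ActiLife raw exports
  (first line starts with dashes and states the sample rate; subsequent
  lines carry start time/date; a dashed line closes the header) followed by
  three acceleration columns in g.

Count series, agreement reports and classification profiles are exchanged
as plain CSV; filters and cut-point scales as JSON.
"""

from __future__ import annotations

import io as _io
import json
import re
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .classify import CutpointScale, IntensityProfile, scale_from_json, scale_to_json
from .counts import CountSeries, RawAcceleration
from .filters import AnyFilter, FrequencyResponse, filter_from_json, filter_to_json

__all__ = [
    "read_raw_csv",
    "write_raw_csv",
    "write_actigraph_raw_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_reference_response_csv",
    "write_reference_response_csv",
    "load_filter_json",
    "save_filter_json",
    "load_scale_json",
    "save_scale_json",
    "write_profile_csvs",
]

PathLike = Union[str, Path]

_AG_RATE_RE = re.compile(r"at\s+(\d+(?:\.\d+)?)\s*Hz", re.IGNORECASE)


def _sniff_actigraph(first_line: str) -> bool:
    return first_line.startswith("---")


def read_raw_csv(
    path: PathLike,
    fs: float | None = None,
    units: str = "g",
    dialect: str = "auto",
) -> RawAcceleration:
    """Read a raw tri-axial CSV in either supported dialect.

    ``dialect`` is ``"generic"``, ``"actigraph"`` or ``"auto"`` (sniffed
    from the first line).  For the generic dialect without a ``time``
    column, ``fs`` is required.  The ActiGraph dialect carries its own
    sampling rate; an ``fs`` argument that contradicts it is an error.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if dialect == "auto":
        dialect = "actigraph" if _sniff_actigraph(first) else "generic"
    if dialect == "actigraph":
        return _read_actigraph(path, fs)
    if dialect != "generic":
        raise ValueError(f"unknown dialect {dialect!r}; expected 'generic' or 'actigraph'")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"x", "y", "z"} <= set(df.columns):
        raise ValueError(f"{path}: generic dialect needs columns x,y,z (optionally time)")
    if fs is None:
        if "time" not in df.columns:
            raise ValueError(f"{path}: sampling rate required (no time column to infer it from)")
        dt = np.median(np.diff(df["time"].to_numpy(dtype=float)))
        if dt <= 0:
            raise ValueError(f"{path}: cannot infer sampling rate from non-increasing time column")
        fs = 1.0 / dt
    return RawAcceleration(
        fs=fs, ax=df["x"].to_numpy(), ay=df["y"].to_numpy(), az=df["z"].to_numpy(), units=units
    )


def _read_actigraph(path: Path, fs: float | None) -> RawAcceleration:
    header: list[str] = []
    with open(path) as fh:
        for line in fh:
            header.append(line.rstrip("\n"))
            if len(header) > 1 and line.startswith("---"):
                break
            if len(header) > 30:
                raise ValueError(f"{path}: ActiGraph header not terminated by a dashed line")
        body = fh.read()
    m = _AG_RATE_RE.search(header[0])
    if not m:
        raise ValueError(f"{path}: could not find the sample rate in the ActiGraph header")
    header_fs = float(m.group(1))
    if fs is not None and not np.isclose(fs, header_fs):
        raise ValueError(f"{path}: requested fs {fs} Hz contradicts header fs {header_fs} Hz")
    start_time = None
    st = sd = None
    for line in header:
        if line.lower().startswith("start time"):
            st = line.split(None, 2)[-1].strip()
        elif line.lower().startswith("start date"):
            sd = line.split(None, 2)[-1].strip()
    if st or sd:
        start_time = " ".join(x for x in (sd, st) if x)
    df = pd.read_csv(_io.StringIO(body))
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected three acceleration columns after the header")
    arr = df.iloc[:, :3].to_numpy(dtype=float)
    return RawAcceleration(
        fs=header_fs, ax=arr[:, 0], ay=arr[:, 1], az=arr[:, 2], units="g",
        start_time=start_time,
    )


def write_raw_csv(raw: RawAcceleration, path: PathLike, time_column: bool = True) -> None:
    """Write a generic-dialect raw CSV (optionally with a time column)."""
    cols = {}
    if time_column:
        cols["time"] = np.arange(raw.n_samples) / raw.fs
    cols.update({"x": raw.ax, "y": raw.ay, "z": raw.az})
    pd.DataFrame(cols).to_csv(path, index=False)


def write_actigraph_raw_csv(raw: RawAcceleration, path: PathLike) -> None:
    """Write a synthetic ActiGraph-RAW-style CSV (header + three columns).

    The header mimics the ActiLife raw-export layout closely enough for
    round-tripping through :func:`read_raw_csv`; it does not claim to come
    from any real device.
    """
    if raw.units != "g":
        raise ValueError("ActiGraph raw exports are in g; convert the signal first")
    fs = raw.fs
    fs_txt = f"{fs:g}"
    lines = [
        f"------------ Data File Created By actcounts synthetic writer "
        f"date format M/d/yyyy at {fs_txt} Hz  Filter Normal -----------",
        "Serial Number: SYN0000000",
        f"Start Time {raw.start_time.split()[-1] if raw.start_time else '00:00:00'}",
        "Start Date 1/1/2020",
        "Epoch Period (hh:mm:ss) 00:00:00",
        "Download Time 00:00:00",
        "Download Date 1/1/2020",
        "Current Memory Address: 0",
        "Current Battery Voltage: 4.0     Mode = 12",
        "--------------------------------------------------",
    ]
    df = pd.DataFrame(
        {"Accelerometer X": raw.ax, "Accelerometer Y": raw.ay, "Accelerometer Z": raw.az}
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def write_counts_csv(counts: CountSeries, path: PathLike) -> None:
    """Write ``epoch_index,epoch_start_s,sx,sy,sz,vm3`` rows."""
    counts.to_dataframe().to_csv(path, index=False)


def read_counts_csv(path: PathLike) -> CountSeries:
    df = pd.read_csv(path)
    required = {"epoch_start_s", "sx", "sy", "sz", "vm3"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: counts CSV needs columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"{path}: counts CSV contains no epochs")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    epoch_s = float(np.median(np.diff(starts))) if len(df) > 1 else 1.0
    return CountSeries(
        epoch_s=epoch_s,
        sx=df["sx"].to_numpy(),
        sy=df["sy"].to_numpy(),
        sz=df["sz"].to_numpy(),
        vm3=df["vm3"].to_numpy(),
        fs_source=0.0,
    )


def read_reference_response_csv(path: PathLike) -> FrequencyResponse:
    """Read a 2-column ``freq_hz,magnitude_db`` table (one header line)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns freq_hz,magnitude_db")
    return FrequencyResponse(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )


def write_reference_response_csv(resp: FrequencyResponse, path: PathLike) -> None:
    pd.DataFrame({"freq_hz": resp.freqs_hz, "magnitude_db": resp.magnitude_db}).to_csv(
        path, index=False
    )


def load_filter_json(path: PathLike) -> AnyFilter:
    with open(path) as fh:
        return filter_from_json(json.load(fh))


def save_filter_json(filt: AnyFilter, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(filter_to_json(filt), fh, indent=1)


def load_scale_json(path: PathLike) -> CutpointScale:
    with open(path) as fh:
        return scale_from_json(json.load(fh))


def save_scale_json(scale: CutpointScale, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(scale_to_json(scale), fh, indent=1)


def write_profile_csvs(
    profile: IntensityProfile, summary_path: PathLike, detail_path: PathLike | None = None
) -> None:
    """Write the per-category summary and, optionally, per-epoch detail."""
    profile.summary_dataframe().to_csv(summary_path, index=False)
    if detail_path is not None:
        profile.detail_dataframe().to_csv(detail_path, index=False)
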