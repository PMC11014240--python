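"""Delimited-text serialization for traces, fiducials and run manifests.

A trace at ``t.csv`` is accompanied by ``t.fiducials.csv`` (cycle_index,
marker, time_s) and ``t.manifest.json`` (the fully resolved configuration,
sufficient to regenerate the trace bit-for-bit).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from cwmsim.trace import Trace

_COLUMN_FOR_UNITS = {"displacement": "displacement_mm", "velocity": "velocity"}


class TraceFormatError(ValueError):
    """A trace file is malformed."""


def fiducials_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".fiducials.csv")


def manifest_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".manifest.json")


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as CSV; fiducials and manifest go to sibling files.

    Columns: time_s, then displacement_mm and/or velocity.  A displacement
    trace carrying its source velocity in ``meta["velocity"]`` gets both.
    """
    path = Path(path)
    main_col = _COLUMN_FOR_UNITS.get(trace.units, trace.units)
    velocity = trace.meta.get("velocity")
    header = ["time_s", main_col]
    columns = [trace.times, trace.samples]
    if trace.units == "displacement" and velocity is not None:
        velocity = np.asarray(velocity, dtype=float)
        if velocity.size == trace.n:
            header.append("velocity")
            columns.append(velocity)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in zip(*columns):
            writer.writerow([repr(float(v)) for v in row])

    if trace.fiducials:
        with fiducials_path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cycle_index", "marker", "time_s"])
            for cycle, marker, time_s in trace.fiducials:
                writer.writerow([cycle, marker, repr(float(time_s))])

    manifest = {
        "tool": "cwmsim",
        "n_samples": trace.n,
        "fs": trace.fs,
        "units": trace.units,
        "scale": trace.scale,
        "cycle_bounds": list(trace.cycle_bounds),
    }
    manifest.update({k: v for k, v in trace.meta.items() if k != "velocity"})
    manifest_path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


def read_trace(path: str | Path) -> Trace:
    """Read a delimited-text trace written by :func:`write_trace`.

    Malformed rows and non-monotone time columns are reported with their
    line number.  Fiducials are read from the sibling file when present.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if not header or header[0] != "time_s":
            raise TraceFormatError(
                f"{path}: expected header starting with 'time_s', got {header}")
        channels = header[1:]
        if not channels:
            raise TraceFormatError(
                f"{path}: expected at least one signal column "
                f"(displacement_mm or velocity)")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise TraceFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: {exc}") from exc
    if len(rows) < 2:
        raise TraceFormatError(f"{path}: need at least 2 data rows")
    data = np.asarray(rows)
    times = data[:, 0]
    dt = np.diff(times)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise TraceFormatError(
            f"{path}:{bad + 3}: time column is not strictly increasing")
    fs = 1.0 / float(np.median(dt))

    if "displacement_mm" in channels:
        samples = data[:, 1 + channels.index("displacement_mm")]
        units, scale = "displacement", "mm"
    else:
        samples = data[:, 1 + channels.index("velocity")]
        units, scale = "velocity", "normalized"
    meta = {}
    if units == "displacement" and "velocity" in channels:
        meta["velocity"] = data[:, 1 + channels.index("velocity")]

    fiducials = []
    fpath = fiducials_path(path)
    if fpath.exists():
        with fpath.open(newline="") as fh:
            reader = csv.reader(fh)
            next(reader, None)
            for row in reader:
                if row:
                    fiducials.append((int(row[0]), row[1], float(row[2])))
    return Trace(samples=samples, fs=fs, units=units, scale=scale,
                 fiducials=fiducials, meta=meta)
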