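"""Delimited-text readers and writers.

Flow curves are the canonical interchange object of the package, stored as
two-column tab-delimited text with a one-line header and the cycle length
in a leading comment::

    # cycle_ms = 1000.0
    time_ms\tflow_ml_s
    0.0\t0.0
    25.0\t1.2
    ...

Centre lines are three-column text (x_mm, y_mm, z_mm per row).  Round
trips preserve values to full double precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .centerline import Centerline
from .curves import FlowCurve
from .errors import FormatError

__all__ = [
    "read_flow_curve",
    "write_flow_curve",
    "read_centerline",
    "write_centerline",
    "read_pairs",
]

_CURVE_HEADER = "time_ms\tflow_ml_s"


def write_flow_curve(curve: FlowCurve, path) -> None:
    """Write a flow curve in the shared delimited-text format."""
    lines = [f"# cycle_ms = {float(curve.cycle_ms)!r}", _CURVE_HEADER]
    lines += [f"{float(t)!r}\t{float(f)!r}"
              for t, f in zip(curve.times, curve.flows)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flow_curve(path) -> FlowCurve:
    """Read a flow curve; raises :class:`FormatError` naming the offending
    line on malformed input."""
    cycle_ms = None
    times, flows = [], []
    last_t = -np.inf
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("cycle_ms"):
                    try:
                        cycle_ms = float(body.split("=", 1)[1])
                    except (IndexError, ValueError):
                        raise FormatError("unreadable cycle_ms comment", lineno)
                continue
            if line.lower().replace(" ", "").startswith("time_ms"):
                continue  # header
            fields = line.replace(",", "\t").split()
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 columns, found {len(fields)}", lineno
                )
            try:
                t, f = float(fields[0]), float(fields[1])
            except ValueError:
                raise FormatError(f"non-numeric value in {fields}", lineno)
            if not (np.isfinite(t) and np.isfinite(f)):
                raise FormatError("non-finite value", lineno)
            if t <= last_t:
                raise FormatError(
                    f"time {t} ms does not increase past {last_t} ms", lineno
                )
            last_t = t
            times.append(t)
            flows.append(f)
    if cycle_ms is None:
        raise FormatError("missing '# cycle_ms = ...' comment line")
    if len(times) < 4:
        raise FormatError(f"only {len(times)} data rows; need at least 4")
    return FlowCurve(times=np.array(times), flows=np.array(flows),
                     cycle_ms=cycle_ms)


def write_centerline(line: Centerline, path) -> None:
    """Write a centre line as x_mm, y_mm, z_mm rows."""
    rows = ["x_mm\ty_mm\tz_mm"]
    rows += [f"{float(x)!r}\t{float(y)!r}\t{float(z)!r}"
             for x, y, z in line.points]
    Path(path).write_text("\n".join(rows) + "\n")


def read_centerline(path) -> Centerline:
    """Read a centre line from three-column delimited text."""
    points = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("x_mm"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) != 3:
                raise FormatError(
                    f"expected 3 columns, found {len(fields)}", lineno
                )
            try:
                points.append([float(v) for v in fields])
            except ValueError:
                raise FormatError(f"non-numeric value in {fields}", lineno)
    if len(points) < 2:
        raise FormatError("a centre line needs at least 2 points")
    return Centerline(points=np.array(points))


def read_pairs(path) -> tuple[np.ndarray, np.ndarray]:
    """Read two-column paired measurements (for agreement analysis)."""
    a, b = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 columns, found {len(fields)}", lineno
                )
            try:
                a.append(float(fields[0]))
                b.append(float(fields[1]))
            except ValueError:
                continue  # header row
    if len(a) < 2:
        raise FormatError("need at least 2 data rows")
    return np.array(a), np.array(b)
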