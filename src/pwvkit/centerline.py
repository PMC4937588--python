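"""Aortic centre-line geometry: pulse-wave travel distance between the
two flow measurement planes.

The centre line is an ordered 3D polyline in patient-space millimetres,
first point on the ascending-aorta plane and last point on the
diaphragm-level plane.  Its length is the distance the pulse wave travels
and the numerator of the PWV.  Any image-to-patient transform is applied
by the reader; geometry here is pure Euclidean.

For sparse manually clicked points a cubic-spline arc length is available
as an alternative to the polyline sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad_vec
from scipy.interpolate import CubicSpline

from .errors import InputError

__all__ = ["Centerline", "centerline_length"]


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D points in mm along the aortic lumen centre."""

    points: np.ndarray  # (N, 3)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InputError(f"points must have shape (N, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise InputError("a centre line needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise InputError("centre-line points must be finite")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
            raise InputError("consecutive centre-line points must be distinct")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return int(self.points.shape[0])


def centerline_length(line: Centerline, spline: bool = False) -> float:
    """Pulse-wave travel distance in mm along the centre line.

    Parameters
    ----------
    spline : bool
        When False (default), sum of Euclidean segment lengths.  When
        True, arc length of a natural cubic spline through the points
        (parametrised by cumulative chord length) — useful when the line
        was clicked sparsely and the polyline underestimates the curve.
    """
    pts = line.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if not spline or line.n < 3:
        return float(seg.sum())
    s = np.concatenate([[0.0], np.cumsum(seg)])
    curve = CubicSpline(s, pts, axis=0)
    deriv = curve.derivative()
    speed = lambda u: np.linalg.norm(deriv(u))
    length, _ = quad_vec(speed, 0.0, s[-1], epsabs=1e-8, epsrel=1e-10)
    return float(length)
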