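"""The :class:`FlowCurve` container — sampled flow versus time over one
cardiac cycle.

A flow curve is the object everything in pwvkit operates on: flow rate in
ml/s sampled at strictly increasing times in ms within ``[0, cycle_ms)``.
Curves produced by the waveform generator and the resamplers are uniformly
sampled starting at t = 0 with spacing ``cycle_ms / n``; curves extracted
from images inherit whatever frame times the acquisition used.

Units are fixed throughout the package: time in ms, flow in ml/s, distance
in mm, velocity (PWV) in m/s.  mm divided by ms is numerically equal to m/s,
so no unit conversion appears anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["FlowCurve"]

_MIN_SAMPLES = 4


@dataclass(frozen=True)
class FlowCurve:
    """Flow rate sampled over one cardiac cycle.

    Parameters
    ----------
    times : array of float
        Sample times in ms, strictly increasing, all in ``[0, cycle_ms)``.
    flows : array of float
        Flow rate in ml/s at each sample time.
    cycle_ms : float
        Cardiac cycle length in ms.  The cycle is treated as periodic
        (retrospective gating reconstructs a closed cycle), so
        ``flows[0]`` is also the value at ``t = cycle_ms``.
    """

    times: np.ndarray
    flows: np.ndarray
    cycle_ms: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        object.__setattr__(self, "cycle_ms", float(self.cycle_ms))
        if times.ndim != 1 or flows.ndim != 1:
            raise InputError("times and flows must be one-dimensional")
        if times.size != flows.size:
            raise InputError(
                f"times ({times.size}) and flows ({flows.size}) differ in length"
            )
        if times.size < _MIN_SAMPLES:
            raise InputError(
                f"a flow curve needs at least {_MIN_SAMPLES} samples, got {times.size}"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(flows))):
            raise InputError("times and flows must be finite")
        if self.cycle_ms <= 0 or not np.isfinite(self.cycle_ms):
            raise InputError(f"cycle_ms must be positive, got {self.cycle_ms}")
        if np.any(np.diff(times) <= 0):
            raise InputError("times must be strictly increasing")
        if times[0] < 0 or times[-1] >= self.cycle_ms:
            raise InputError("times must lie within [0, cycle_ms)")

    @property
    def n(self) -> int:
        """Number of time frames."""
        return int(self.times.size)

    @property
    def is_uniform(self) -> bool:
        """True if the samples sit on the canonical uniform grid
        ``t_k = k * cycle_ms / n``."""
        expected = np.arange(self.n) * (self.cycle_ms / self.n)
        return bool(np.allclose(self.times, expected, rtol=0.0,
                                atol=1e-9 * self.cycle_ms))

    @property
    def dt(self) -> float:
        """Uniform sample spacing in ms (``cycle_ms / n``)."""
        if not self.is_uniform:
            raise InputError("curve is not uniformly sampled")
        return self.cycle_ms / self.n

    @classmethod
    def uniform(cls, flows: np.ndarray, cycle_ms: float) -> "FlowCurve":
        """Build a curve on the canonical uniform grid from flow values."""
        flows = np.asarray(flows, dtype=float)
        times = np.arange(flows.size) * (float(cycle_ms) / flows.size)
        return cls(times=times, flows=flows, cycle_ms=cycle_ms)

    def with_flows(self, flows: np.ndarray) -> "FlowCurve":
        """Return a copy with the same time grid and new flow values."""
        return FlowCurve(times=self.times.copy(), flows=np.asarray(flows, float),
                         cycle_ms=self.cycle_ms)
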