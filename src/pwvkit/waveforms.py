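"""Synthetic aortic flow waveforms and phantom curve pairs.

Real through-plane aortic flow curves show a flat (near-zero) diastolic
baseline, a steep systolic upstroke, and a decay back to baseline by end
of ejection.  The generator here models that shape parametrically as a
flat baseline plus a raised-cosine pulse:

* flat at ``diastolic_level`` outside the ejection window,
* a half raised-cosine rise from the foot at ``foot_time`` to the peak at
  ``foot_time + upslope_duration``,
* a half raised-cosine decay back to baseline at
  ``foot_time + ejection_duration``.

Both cosine halves have zero slope at their endpoints, so the waveform is
continuously differentiable everywhere (C1) and its single first-derivative
maximum sits at the midpoint of the upslope — the feature the time-to-foot
tangent method keys on.  The closed-form cycle integral is
``diastolic_level * cycle + (peak - diastolic) * ejection_duration / 2``.

Phantom pairs emulate a pulse wave travelling between two measurement
planes: given a true PWV and an inter-plane distance, the distal curve is
the proximal waveform delayed by ``distance / PWV`` (mm / (m/s) = ms).  The
delay is circular over the periodic cycle and is applied analytically on
the dense evaluation grid, before any downsampling, so the injected
transit time is exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import FlowCurve
from .errors import InputError, ParameterError

__all__ = ["WaveformParams", "generate_waveform", "make_phantom_pair"]


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the synthetic aortic flow waveform.

    Defaults describe a normal resting adult: 60 beats per minute, 400 ml/s
    peak aortic flow, systolic upstroke starting 80 ms after the R-wave,
    reaching its peak 90 ms later, with ejection complete 300 ms after the
    foot, and zero diastolic flow.
    """

    heart_rate: float = 60.0        # beats per minute
    peak_flow: float = 400.0        # ml/s
    foot_time: float = 80.0         # ms after cycle start (upstroke onset)
    upslope_duration: float = 90.0  # ms, foot to peak
    ejection_duration: float = 300.0  # ms, foot to return-to-baseline
    diastolic_level: float = 0.0    # ml/s
    noise_sd: float = 0.0           # ml/s, additive white Gaussian noise
    seed: int | None = None

    @property
    def cycle_ms(self) -> float:
        return 60000.0 / self.heart_rate

    def validate(self) -> None:
        if self.heart_rate <= 0:
            raise ParameterError(f"heart_rate must be > 0, got {self.heart_rate}")
        if self.foot_time < 0:
            raise ParameterError(f"foot_time must be >= 0, got {self.foot_time}")
        if not 0 < self.upslope_duration < self.ejection_duration:
            raise ParameterError(
                "need 0 < upslope_duration < ejection_duration, got "
                f"{self.upslope_duration} and {self.ejection_duration}"
            )
        if self.foot_time + self.ejection_duration > self.cycle_ms:
            raise ParameterError(
                "ejection must end within the cycle: foot_time + "
                f"ejection_duration = {self.foot_time + self.ejection_duration}"
                f" ms > cycle {self.cycle_ms} ms"
            )
        if self.peak_flow <= self.diastolic_level:
            raise ParameterError(
                f"peak_flow ({self.peak_flow}) must exceed diastolic_level "
                f"({self.diastolic_level})"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the noiseless periodic waveform at arbitrary times (ms)."""
        t = np.asarray(t_ms, dtype=float) % self.cycle_ms
        x = t - self.foot_time
        up, ej = self.upslope_duration, self.ejection_duration
        amp = self.peak_flow - self.diastolic_level
        flows = np.full_like(t, self.diastolic_level)

        rise = (x >= 0) & (x < up)
        flows[rise] += amp * 0.5 * (1.0 - np.cos(np.pi * x[rise] / up))
        fall = (x >= up) & (x < ej)
        flows[fall] += amp * 0.5 * (1.0 + np.cos(np.pi * (x[fall] - up) / (ej - up)))
        return flows

    def cycle_integral(self) -> float:
        """Closed-form integral of the noiseless waveform over one cycle
        (ml/s · ms)."""
        amp = self.peak_flow - self.diastolic_level
        return self.diastolic_level * self.cycle_ms + amp * self.ejection_duration / 2.0


def generate_waveform(params: WaveformParams, n_frames: int) -> FlowCurve:
    """Sample the synthetic waveform at ``n_frames`` uniform points.

    With ``noise_sd > 0``, adds white Gaussian noise reproducible from
    ``params.seed``; with ``noise_sd = 0`` the seed is irrelevant.
    """
    params.validate()
    if n_frames < 4:
        raise InputError(f"n_frames must be >= 4, got {n_frames}")
    cycle = params.cycle_ms
    times = np.arange(n_frames) * (cycle / n_frames)
    flows = params.evaluate(times)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        flows = flows + rng.normal(0.0, params.noise_sd, size=n_frames)
    return FlowCurve(times=times, flows=flows, cycle_ms=cycle)


def make_phantom_pair(
    params: WaveformParams,
    pwv_true: float,
    distance: float,
    n_frames: int,
    dense_n: int = 10_000,
) -> tuple[FlowCurve, FlowCurve, float]:
    """Build a proximal/distal phantom curve pair with a known injected PWV.

    Parameters
    ----------
    pwv_true : float
        True pulse wave velocity in m/s; must be > 0.
    distance : float
        Distance between the two flow measurement planes in mm; must be > 0.
    n_frames : int
        Number of acquired time frames for the returned pair.  If below
        ``dense_n`` the dense curves are downsampled with the anti-aliased
        resampler; ``n_frames == dense_n`` returns the dense curves.
    dense_n : int
        Dense evaluation grid size (default 10 000 frames per cycle, i.e.
        0.1 ms at 60 bpm).

    Returns
    -------
    (proximal, distal, shift_ms)
        The two curves and the injected transit time ``distance / pwv_true``
        in ms.
    """
    from .resampling import downsample_antialiased  # deferred: avoids cycle

    params.validate()
    if pwv_true <= 0:
        raise ParameterError(f"pwv_true must be > 0, got {pwv_true}")
    if distance <= 0:
        raise ParameterError(f"distance must be > 0, got {distance}")
    shift_ms = distance / pwv_true  # mm / (m/s) = ms
    if shift_ms >= params.cycle_ms:
        raise ParameterError(
            f"injected shift {shift_ms:.1f} ms is not below the cycle "
            f"length {params.cycle_ms:.1f} ms"
        )
    if not 4 <= n_frames <= dense_n:
        raise InputError(f"n_frames must be in [4, dense_n={dense_n}], got {n_frames}")

    cycle = params.cycle_ms
    t_dense = np.arange(dense_n) * (cycle / dense_n)
    prox_flows = params.evaluate(t_dense)
    dist_flows = params.evaluate(t_dense - shift_ms)  # circular delay
    if params.noise_sd > 0:
        seq = np.random.SeedSequence(params.seed)
        rng_p, rng_d = (np.random.default_rng(s) for s in seq.spawn(2))
        prox_flows = prox_flows + rng_p.normal(0.0, params.noise_sd, dense_n)
        dist_flows = dist_flows + rng_d.normal(0.0, params.noise_sd, dense_n)

    proximal = FlowCurve(times=t_dense, flows=prox_flows, cycle_ms=cycle)
    distal = FlowCurve(times=t_dense, flows=dist_flows, cycle_ms=cycle)
    if n_frames < dense_n:
        proximal = downsample_antialiased(proximal, n_frames)
        distal = downsample_antialiased(distal, n_frames)
    return proximal, distal, shift_ms
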