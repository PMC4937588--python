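"""Time-to-foot (TTF) pulse wave velocity from paired flow curves.

The foot of a flow curve is located by intersecting tangents: a regression
line fitted to the maximal systolic upslope is intersected with a baseline
tangent fitted to late diastole, and the intersection time is the foot.
The transit time between the feet of a proximal (ascending aorta) and a
distal (diaphragm-level) curve, divided into the centre-line distance
between the two planes, gives the pulse wave velocity:

    PWV [m/s] = distance [mm] / delta_t [ms]

Algorithm details (all configurable through :class:`TtfConfig`):

* the acquired curve is interpolated to a dense uniform grid (default
  0.1 ms) by periodic cubic splines and then smoothed with a Gaussian
  kernel (default sigma 0.025 acquired frame intervals, i.e. 0.62 ms at
  40 frames / 60 bpm — a width that only acts on the interpolated grid);
  tangents are fitted on this dense curve, which is what makes
  sub-frame-interval transit times resolvable at clinical frame counts;
* the upslope is anchored at the sample of maximum first difference
  (earliest wins on ties); the regression window is the contiguous run of
  samples whose flow lies between 20 % and 80 % of the peak-to-baseline
  amplitude, widened symmetrically to at least 3 samples;
* the baseline tangent is a horizontal line at the mean flow over a
  pre-upstroke window (default one tenth of the cycle) ending where the
  curve last sits near its diastolic minimum before the upstroke; a
  sloped baseline fit is available behind a flag;
* transit times are computed modulo the cycle and mapped into
  ``(-cycle/2, cycle/2]``; non-positive values raise
  :class:`~pwvkit.errors.NonPhysiologicTransitTime` rather than being
  silently flipped.

Flow curves may additionally carry a constant baseline offset from eddy
current background phase errors.  ``auto_baseline_offset`` estimates it as
the mean flow during 62.5–87.5 % of the cycle (late diastole); a manual
offset path exists because the automatic window fails with significant
aortic regurgitation, where diastolic flow is genuinely non-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import FlowCurve
from .errors import (
    DegenerateTangentsError,
    InputError,
    NonPhysiologicTransitTime,
    NoUpstrokeError,
    ParameterError,
)
from .resampling import SmoothingSpec, gaussian_smooth, upsample_cubic

__all__ = [
    "TtfConfig",
    "TangentFit",
    "FootResult",
    "PwvResult",
    "detect_foot",
    "transit_time",
    "compute_pwv",
    "auto_baseline_offset",
    "apply_baseline_correction",
    "measure_pwv",
]


@dataclass(frozen=True)
class TtfConfig:
    """Tunable parameters of the intersecting-tangent foot detector."""

    #: flow band of the upslope regression window, as fractions of the
    #: peak-to-baseline amplitude
    upslope_band: tuple[float, float] = (0.2, 0.8)
    #: minimum number of samples in the upslope regression
    min_upslope_points: int = 3
    #: baseline window length as a fraction of the cycle
    baseline_window_frac: float = 0.10
    #: a sample counts as "near baseline" when its flow is within this
    #: fraction of the curve range above the minimum (used to anchor the
    #: baseline window just before the upstroke)
    onset_frac: float = 0.05
    #: fit the baseline tangent with a free slope instead of horizontal
    fit_baseline_slope: bool = False
    #: curves whose range is below this (ml/s) have no detectable upstroke
    noise_floor: float = 1e-9
    #: internal grid spacing (ms) the curve is interpolated to before
    #: tangent fitting; curves already at least this fine are used as-is
    interp_dt_ms: float = 0.1
    #: Gaussian smoothing applied before tangent fitting
    smoothing: SmoothingSpec = field(
        default_factory=lambda: SmoothingSpec(sigma_frac=0.025)
    )
    #: baseline correction mode: "off", "auto", or "manual"
    baseline_mode: str = "off"
    #: offset in ml/s used when baseline_mode == "manual"
    manual_offset: float = 0.0

    def __post_init__(self):
        lo, hi = self.upslope_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ParameterError(f"invalid upslope band {self.upslope_band}")
        if self.min_upslope_points < 2:
            raise ParameterError("min_upslope_points must be >= 2")
        if not 0.0 < self.baseline_window_frac < 0.5:
            raise ParameterError("baseline_window_frac must be in (0, 0.5)")
        if self.baseline_mode not in ("off", "auto", "manual"):
            raise ParameterError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.interp_dt_ms <= 0:
            raise ParameterError("interp_dt_ms must be > 0")


@dataclass(frozen=True)
class TangentFit:
    """A fitted tangent line: ``flow = slope * t + intercept``."""

    slope: float          # ml/s per ms
    intercept: float      # ml/s at t = 0
    fit_window: tuple[float, float]  # [ms, ms], within the unwrapped cycle
    r_squared: float

    def value_at(self, t_ms: float) -> float:
        return self.slope * t_ms + self.intercept


@dataclass(frozen=True)
class FootResult:
    """Foot time of one flow curve with its two tangent diagnostics."""

    foot_time: float      # ms, in [0, cycle)
    upslope: TangentFit
    baseline: TangentFit


@dataclass(frozen=True)
class PwvResult:
    """End-to-end PWV measurement with per-curve diagnostics."""

    delta_t: float        # ms
    distance: float       # mm
    pwv: float            # m/s
    proximal_foot: FootResult
    distal_foot: FootResult


def _least_squares_line(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of an ordinary least-squares line."""
    slope, intercept = np.polyfit(t, f, 1)
    resid = f - (slope * t + intercept)
    ss_tot = np.sum((f - f.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def detect_foot(
    curve: FlowCurve,
    smoothing: SmoothingSpec | None = None,
    config: TtfConfig | None = None,
) -> FootResult:
    """Locate the foot of a flow curve by intersecting tangents.

    Parameters
    ----------
    curve : FlowCurve
        Uniformly sampled curve containing one systolic upstroke.
    smoothing : SmoothingSpec, optional
        Overrides ``config.smoothing`` when given.
    config : TtfConfig, optional
        Detector parameters; defaults are clinical defaults.

    Raises
    ------
    NoUpstrokeError
        If the curve has no positive-slope region above the noise floor.
    DegenerateTangentsError
        If the upslope and baseline tangents are near-parallel.
    """
    config = config or TtfConfig()
    spec = smoothing if smoothing is not None else config.smoothing
    # sigma_frac is a fraction of the *acquired* frame interval, so resolve
    # it against the input grid before any internal interpolation
    sigma_ms = spec.resolve(curve.cycle_ms, curve.n)
    n_dense = int(round(curve.cycle_ms / config.interp_dt_ms))
    if curve.n < n_dense:
        curve = upsample_cubic(curve, n_dense)
    curve = gaussian_smooth(curve, SmoothingSpec(sigma_ms=sigma_ms))

    f = curve.flows
    n = curve.n
    dt = curve.dt
    cycle = curve.cycle_ms
    frange = float(f.max() - f.min())
    if frange <= config.noise_floor:
        raise NoUpstrokeError(
            f"curve range {frange:.3g} ml/s is at or below the noise floor"
        )

    # Anchor: sample of maximum circular first difference; earliest on ties.
    diffs = np.roll(f, -1) - f
    i_max = int(np.argmax(diffs))
    if diffs[i_max] <= 0:
        raise NoUpstrokeError("no positive-slope region found")

    def fx(j: int) -> float:
        return float(f[j % n])

    # Upstroke onset: walk back from the anchor to where the curve last sits
    # near its diastolic minimum.  Keeps the baseline window clear of the
    # upslope and makes the detector equivariant under circular time shifts.
    fmin = float(f.min())
    onset_level = fmin + config.onset_frac * frange
    j = i_max
    for _ in range(n):
        if fx(j) <= onset_level:
            break
        j -= 1
    onset_idx = j  # unwrapped (may be negative)

    # Baseline tangent over the window ending at the onset sample.
    w = max(2, int(round(config.baseline_window_frac * n)))
    base_idx = np.arange(onset_idx - w + 1, onset_idx + 1)
    t_base = base_idx * dt
    f_base = f[base_idx % n]
    if config.fit_baseline_slope:
        b_slope, b_int, b_r2 = _least_squares_line(t_base, f_base)
    else:
        b_slope, b_int, b_r2 = 0.0, float(f_base.mean()), 1.0
    baseline = TangentFit(
        slope=b_slope, intercept=b_int,
        fit_window=(float(t_base[0]), float(t_base[-1])), r_squared=b_r2,
    )

    # Upslope regression window: contiguous in-band run around the anchor.
    level = b_int + b_slope * (i_max * dt) if config.fit_baseline_slope else b_int
    amp = float(f.max()) - level
    if amp <= 0:
        raise NoUpstrokeError("peak does not rise above the baseline level")
    lo = level + config.upslope_band[0] * amp
    hi = level + config.upslope_band[1] * amp

    a = b = i_max
    if fx(a) > hi:           # anchor above the band: slide down the upstroke
        while a > i_max - n and fx(a - 1) > hi:
            a -= 1
        a -= 1
        b = a
    elif fx(a) < lo:         # anchor below the band: slide up
        while b < i_max + n and fx(b + 1) < lo:
            b += 1
        b += 1
        a = b
    while a - 1 > i_max - n and lo <= fx(a - 1) <= hi:
        a -= 1
    while b + 1 < i_max + n and lo <= fx(b + 1) <= hi:
        b += 1
    # Coarse acquisitions may leave fewer than min_upslope_points samples in
    # the band; widen to the side whose next sample is closest to the band.
    while b - a + 1 < config.min_upslope_points:
        d_left = max(lo - fx(a - 1), fx(a - 1) - hi, 0.0)
        d_right = max(lo - fx(b + 1), fx(b + 1) - hi, 0.0)
        if d_left <= d_right:
            a -= 1
        else:
            b += 1

    up_idx = np.arange(a, b + 1)
    t_up = up_idx * dt
    u_slope, u_int, u_r2 = _least_squares_line(t_up, f[up_idx % n])
    if u_slope <= 0:
        raise NoUpstrokeError("upslope regression has non-positive slope")
    upslope = TangentFit(
        slope=u_slope, intercept=u_int,
        fit_window=(float(t_up[0]), float(t_up[-1])), r_squared=u_r2,
    )

    denom = u_slope - b_slope
    scale = frange / dt  # typical slope magnitude for the parallel test
    if abs(denom) < 1e-9 * scale:
        raise DegenerateTangentsError(
            "upslope and baseline tangents are near-parallel"
        )
    t_foot = (b_int - u_int) / denom
    return FootResult(foot_time=float(t_foot % cycle), upslope=upslope,
                      baseline=baseline)


def transit_time(proximal: FootResult, distal: FootResult, cycle_ms: float) -> float:
    """Transit time between two feet, mapped into ``(-cycle/2, cycle/2]``.

    Raises :class:`NonPhysiologicTransitTime` when the result is zero or
    negative; the exception carries the value.
    """
    p = proximal.foot_time if isinstance(proximal, FootResult) else float(proximal)
    d = distal.foot_time if isinstance(distal, FootResult) else float(distal)
    delta = (d - p) % cycle_ms
    if delta > cycle_ms / 2.0:
        delta -= cycle_ms
    if delta <= 0.0:
        raise NonPhysiologicTransitTime(delta)
    return float(delta)


def compute_pwv(distance: float, delta_t: float) -> float:
    """PWV in m/s from a distance in mm and a transit time in ms."""
    if distance <= 0:
        raise ParameterError(f"distance must be > 0, got {distance}")
    if delta_t <= 0:
        raise NonPhysiologicTransitTime(delta_t)
    return distance / delta_t


def auto_baseline_offset(curve: FlowCurve) -> float:
    """Baseline offset as the mean flow during 62.5–87.5 % of the cycle."""
    mask = (curve.times >= 0.625 * curve.cycle_ms) & (
        curve.times <= 0.875 * curve.cycle_ms
    )
    if not np.any(mask):
        raise InputError(
            "no samples in the 62.5-87.5 % late-diastolic window; "
            "curve too short"
        )
    return float(curve.flows[mask].mean())


def apply_baseline_correction(curve: FlowCurve, offset: float) -> FlowCurve:
    """Subtract a constant baseline offset (ml/s) from the whole curve."""
    if not np.isfinite(offset):
        raise ParameterError(f"offset must be finite, got {offset}")
    return curve.with_flows(curve.flows - offset)


def _correct(curve: FlowCurve, config: TtfConfig) -> FlowCurve:
    if config.baseline_mode == "auto":
        return apply_baseline_correction(curve, auto_baseline_offset(curve))
    if config.baseline_mode == "manual":
        return apply_baseline_correction(curve, config.manual_offset)
    return curve


def measure_pwv(
    proximal: FlowCurve,
    distal: FlowCurve,
    distance: float,
    config: TtfConfig | None = None,
) -> PwvResult:
    """End-to-end TTF measurement on a proximal/distal curve pair.

    Applies baseline correction (per ``config.baseline_mode``), smooths,
    detects both feet, forms the transit time and divides it into the
    centre-line distance.  All tangent diagnostics are retained in the
    result.
    """
    config = config or TtfConfig()
    if abs(proximal.cycle_ms - distal.cycle_ms) > 1e-9 * proximal.cycle_ms:
        raise InputError(
            f"cycle length mismatch: {proximal.cycle_ms} vs {distal.cycle_ms} ms"
        )
    if distance <= 0:
        raise ParameterError(f"distance must be > 0, got {distance}")

    feet = []
    for label, curve in (("proximal", proximal), ("distal", distal)):
        try:
            feet.append(detect_foot(_correct(curve, config), config=config))
        except (NoUpstrokeError, DegenerateTangentsError) as exc:
            raise type(exc)(f"{label} curve: {exc}") from exc
    prox_foot, dist_foot = feet

    delta_t = transit_time(prox_foot, dist_foot, proximal.cycle_ms)
    pwv = compute_pwv(distance, delta_t)
    return PwvResult(delta_t=delta_t, distance=float(distance), pwv=pwv,
                     proximal_foot=prox_foot, distal_foot=dist_foot)
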