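# Methods

## The measurement model

Pulse wave velocity is estimated as `PWV = D / Δt`, with `D` the aortic
centre-line distance (mm) between the ascending-aorta and diaphragm-level
flow planes and `Δt` the transit time (ms) of the flow wavefront between
them. Units are fixed package-wide (ms, mm, ml/s, m/s); mm/ms is
numerically m/s, so no conversions appear in the code.

`Δt` comes from the time-to-foot method. For each flow curve the *foot*
is the intersection of two tangents:

- an **upslope tangent**: an ordinary least-squares line through the
  samples of the maximal systolic upstroke whose flow lies between 20 %
  and 80 % of the peak-to-baseline amplitude (window anchored at the
  maximum first difference, earliest sample winning ties, widened to at
  least 3 samples);
- a **baseline tangent**: by default a horizontal line at the mean flow
  over a pre-upstroke window covering 10 % of the cycle. A free-slope
  baseline fit is available behind `TtfConfig.fit_baseline_slope`.

The transit time is the difference of the two feet modulo the cycle,
mapped into `(−cycle/2, cycle/2]`. Non-positive values raise
`NonPhysiologicTransitTime` (carrying the value) instead of being
silently flipped: a zero or negative Δt on real data signals mislabelled
planes or a failed foot fit, and should be looked at, not corrected.

### Dense interpolation before tangent fitting

`detect_foot` interpolates the acquired curve to a 0.1 ms grid (periodic
cubic splines) before smoothing and tangent fitting
(`TtfConfig.interp_dt_ms`). This is what makes sub-frame-interval transit
times resolvable: at clinically realistic frame counts (20–40 per cycle)
the 20–80 % amplitude band contains only one to three acquired samples,
and regression lines through so few points jitter by several ms depending
on where the samples happen to fall on the upstroke — enough to produce
order-50 % PWV errors at high PWV, where Δt is ~12 ms against a 25–50 ms
frame interval. Fitting on the interpolated curve reduces the worst error
over 2–20 m/s to a few percent at ≥ 34 frames. The default Gaussian
smoothing width (see below) is itself far below one frame interval, which
only has meaning on such an interpolated grid.

### Smoothing

Before tangent fitting the curve is smoothed with a Gaussian kernel of
standard deviation `sigma_frac = 0.025` acquired frame intervals —
0.625 ms at 40 frames / 60 bpm — entered either as a fraction or as an
absolute `sigma_ms`. Smoothing is implemented in the Fourier domain
(transfer function `exp(−(2πfσ)²/2)`), which is exactly zero-phase,
DC-preserving and correct for sub-sample sigmas; a discrete spatial
kernel of width 0.025 samples would truncate to the identity. On clean
synthetic pairs halving sigma changes the measured PWV by well under
0.1 m/s; the parameter matters only for noisy clinical curves.

### Baseline window choice

The baseline window is placed to *end* where the curve last sits within
5 % of its range above the diastolic minimum before the upstroke
(`TtfConfig.onset_frac`), rather than immediately before the point of
maximum slope: the maximum first difference sits mid-upstroke, so a
window ending there would average in half the rise and bias the baseline
by several ml/s. Anchoring on the near-minimum crossing keeps the window
in true diastole and makes foot detection equivariant under circular time
shifts of the curve.

### Baseline-offset (eddy-current) correction

Background phase errors shift a whole flow curve by a constant. The
automatic estimate is the mean flow during 62.5–87.5 % of the cycle
(late diastole, where true aortic flow is near zero); subtracting it
re-zeroes diastole and the estimate is idempotent. With significant
aortic regurgitation diastolic flow is genuinely negative and the
automatic window mistakes it for offset — hence the manual path
(`baseline_mode="manual"`). Correction is off by default; a constant
offset moves both tangents' intersection only through the upslope-window
selection, so clean curves do not need it.

## The synthetic waveform

The generator models a normal resting aortic flow curve parametrically:
flat diastole at `diastolic_level` plus a raised-cosine pulse — a half
cosine rising from the foot (`foot_time`, default 80 ms after the R-wave)
to the peak (`peak_flow` 400 ml/s at foot + `upslope_duration` 90 ms) and
a half cosine decaying back to baseline at foot + `ejection_duration`
(300 ms), at `heart_rate` 60 bpm. Both cosine halves have zero end
slopes, so the waveform is C1 everywhere and its only first-derivative
maximum is mid-upslope. The cycle integral has the closed form
`diastolic_level·cycle + (peak − diastolic)·ejection/2` (60 ml per beat
at defaults — a normal stroke volume). Optional additive white Gaussian
noise (`noise_sd`, seeded) is off by default, because the phantom study
is about discretisation error, not noise.

What the generator does *not* emulate: reflected waves, regurgitant
shapes, beat-to-beat variability, and the exact spectral content of any
measured subject curve. Consequences: phantom error *magnitudes* at
coarse sampling are waveform-dependent, and passing the plateau check
here shows the method and pipeline behave correctly for a realistic
smooth waveform — not that any particular patient curve yields the same
error table.

A note on foot conventions: the intersecting-tangent foot of a smooth
(raised-cosine) onset lies analytically about `0.16 × upslope_duration`
*after* the onset parameter (≈ 14 ms at defaults). That bias is intrinsic
to the tangent construction, identical for both curves of a pair, and
cancels exactly in Δt; tests therefore check absolute foot positions
against a dense least-squares oracle of the tangent definition, not
against the generator's onset parameter.

## Phantom pairs and the temporal-resolution experiment

A phantom pair is built analytically: the waveform is evaluated on a
dense grid (10 000 frames per cycle, 0.1 ms at 60 bpm) and the distal
curve is the same waveform evaluated at `t − shift` with
`shift = D / PWV_true`, i.e. an exact circular delay of the continuous
periodic waveform (retrospective gating implies periodicity; the circular
delay preserves curve area and needs no edge extrapolation). Both curves
are then downsampled to the acquired frame count.

Downsampling removes all harmonics at or above the target Nyquist
frequency `n_frames / (2·cycle)` in the Fourier domain and resamples —
for a periodic signal this *is* the ideal anti-aliasing filter: exactly
zero-phase (no Δt bias), alias-free, DC-preserving.

The default experiment crosses true PWVs 2–20 m/s (10 steps of 2 m/s)
with 20–40 frames per cycle (21 counts, temporal resolutions 50 down to
25 ms), distance 250 mm — 210 conditions, each measured end-to-end by
`measure_pwv`. Per frame count the table reports the signed median error
(m/s and %), the median and the maximum absolute percentage error; a
failed foot detection is recorded per-condition, never raised. The
**cut-off** is the smallest frame count from which the maximum absolute
percentage error stays within tolerance (default 6 %) for *all* larger
frame counts — a suffix rule, chosen because a single dip below
tolerance followed by a worse row is not a plateau. With the default
waveform the cut-off lands at 34 frames (worst error 3.8 % for ≥ 35
frames); errors peak near 27–28 and 20–21 frames, where the anti-aliased
upstroke is represented by too few genuine samples and the interpolant's
shape depends strongly on sample phase.

Runtime: the full 210-condition grid takes about one second on one core;
all defaults (grid, dense resolution, distance) are the experiment's
definition, not performance compromises.

## Geometry, extraction, agreement

- **Centre line**: ordered 3D patient-space points (mm); distance is the
  polyline length, or optionally the arc length of a cubic spline
  parametrised by cumulative chord length (for sparse manual clicks,
  where the polyline cuts corners). Invariant under rigid motion.
- **Flow extraction**: `flow(t) = Σ_ROI v(t,px) · pixel_area / 100`
  (cm/s, mm² → ml/s). Linear in velocity and additive over disjoint
  masks; per-frame masks supported; velocities above the stated Venc are
  rejected as likely aliased.
- **Bland–Altman**: differences `d = a − b`, bias = mean(d), sample
  (n−1) SD, limits of agreement `bias ± 1.96·SD`. Antisymmetric under
  swapping the methods.

## Numerical choices and edge cases

- Upslope anchor ties: earliest sample wins (deterministic).
- Near-parallel tangents (slope difference < 1e−9 of the curve's typical
  slope) raise `DegenerateTangentsError`.
- Curves with range below `noise_floor` raise `NoUpstrokeError`.
- Table output rounds half away from zero (`round_half_up`), matching
  clinical-table convention (31.25 → 31.3 ms), while machine-readable
  output keeps full precision.
- Flow curves require ≥ 4 samples, finite values, strictly increasing
  times inside `[0, cycle)`.

## Known limitations

- The upslope/baseline window heuristics assume a single systolic
  upstroke per cycle; arrhythmic or biphasic curves are out of scope.
- The automatic baseline window assumes near-zero late-diastolic flow.
- No cross-correlation or flow-area transit-time variants are provided;
  the package implements the intersecting-tangent method only.
- Image ingestion is deliberately minimal (NIfTI volumes + masks);
  vessel segmentation, phase unwrapping and Venc scouting are upstream
  of this package.
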