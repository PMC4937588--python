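# pwvkit

Aortic pulse wave velocity (PWV) from phase-contrast MR flow curves.

PWV — the speed at which the systolic pressure/flow wavefront travels down
the aorta — is a biomarker of arterial stiffness. Phase-contrast CMR
measures it by acquiring through-plane flow curves at two planes (ascending
aorta and aorta at the diaphragm), locating the *foot* of each curve, and
dividing the centre-line distance between the planes by the transit time
between the feet:

```
PWV [m/s] = D [mm] / Δt [ms]
```

The foot is found by the **time-to-foot (TTF) intersecting-tangent
method**: a regression line fitted to the maximal systolic upslope is
intersected with a horizontal baseline tangent fitted to late diastole;
the intersection time is the foot. Because the tangent fit interpolates
between acquired frames, Δt is resolved well below the frame interval —
but only down to a point. The package therefore also ships a
computer-phantom experiment that quantifies, for a given waveform, how
many acquired frames per cardiac cycle the method needs before the PWV
error plateaus.

What's in the box:

- `waveforms` — parametric synthetic aortic flow waveform (flat diastole +
  raised-cosine systolic pulse) and phantom pairs with an exactly known
  injected PWV;
- `resampling` — periodic cubic upsampling, ideal zero-phase anti-aliased
  downsampling, Fourier-domain Gaussian smoothing;
- `ttf` — foot detection, transit time, PWV, automatic (62.5–87.5 % of
  cycle) and manual baseline-offset correction;
- `flowmaps` — flow-curve extraction from through-plane velocity maps +
  ROI masks (NIfTI readable);
- `centerline` — polyline / spline travel distance from 3D centre-line
  points;
- `phantoms` — the temporal-resolution grid experiment and cut-off rule;
- `agreement` — Bland–Altman bias ± SD with 95 % limits of agreement;
- a thin CLI (`pwvkit simulate|measure|phantom|distance|extract|agree`).

## Worked example

```python
from pwvkit import WaveformParams, make_phantom_pair, measure_pwv

params = WaveformParams()          # 60 bpm, peak 400 ml/s, foot at 80 ms
prox, dist, shift = make_phantom_pair(params, pwv_true=6.0,
                                      distance=250.0, n_frames=40)
result = measure_pwv(prox, dist, distance=250.0)
print(f"{shift:.2f} {result.delta_t:.2f} {result.pwv:.3f}")
```

prints

```
41.67 41.70 5.995
```

i.e. the injected 41.67 ms transit time (250 mm at 6 m/s) is recovered as
41.70 ms from the 40-frame pair, giving 5.995 m/s — a 0.1 % error. The
same measurement from the shell:

```sh
pwvkit simulate --pwv 6 --distance 250 --frames 40 --out pair.txt
pwvkit measure pair.txt pair_distal.txt --distance 250
```

`examples/` holds one short script per capability (phantom grid, image
extraction, centre-line distance, agreement statistics), each printing the
numbers it computes and what they mean. Running
`examples/phantom_temporal_resolution.py` evaluates all 210 phantom
conditions (true PWV 2–20 m/s × 20–40 frames) and reports that from 34
frames per cycle the worst absolute PWV error over the whole 2–20 m/s
range stays within 6 %.

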