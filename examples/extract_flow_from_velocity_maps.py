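"""From through-plane velocity maps to a flow curve.

Builds a synthetic phase-contrast series: a circular vessel (12 mm radius)
with a parabolic (Poiseuille) velocity profile whose centre velocity
follows the synthetic flow waveform over the cycle.  Integrating velocity
over the ROI recovers the waveform as a volumetric flow curve.
"""

import numpy as np

from pwvkit import RoiMask, VelocitySeries, WaveformParams, extract_flow_curve

params = WaveformParams()
n_frames, h, w = 40, 64, 64
pixel_mm = 1.0
radius_mm = 12.0
area_mm2 = np.pi * radius_mm**2

yy, xx = np.mgrid[0:h, 0:w]
r2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) * pixel_mm**2
inside = r2 <= radius_mm**2

times = np.arange(n_frames) * params.cycle_ms / n_frames
target_flow = params.evaluate(times)  # ml/s
# Poiseuille: flow = vmax * A / 2  ->  vmax[cm/s] = 2 * flow / A * 100
vmax = 2.0 * target_flow / area_mm2 * 100.0

frames = np.zeros((n_frames, h, w))
for t in range(n_frames):
    frames[t][inside] = vmax[t] * (1.0 - r2[inside] / radius_mm**2)

series = VelocitySeries(frames=frames, pixel_spacing=(pixel_mm, pixel_mm),
                        frame_times=times, venc=200.0)
curve = extract_flow_curve(series, RoiMask(inside))

print(f"target peak flow    : {target_flow.max():.1f} ml/s")
print(f"extracted peak flow : {curve.flows.max():.1f} ml/s")
err = 100.0 * abs(curve.flows.max() - target_flow.max()) / target_flow.max()
print(f"pixelation error    : {err:.1f} %")
# The ~1-2 % gap is the discretisation of the circular ROI on a 1 mm grid,
# not a property of the integration itself.
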