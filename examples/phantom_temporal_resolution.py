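"""How many time frames per cycle does an accurate PWV need?

Runs the full phantom grid — true PWV 2-20 m/s (10 steps) crossed with
20-40 acquired frames per cycle (21 steps, i.e. 210 conditions) — and
prints the per-frame-count error table plus the frame-count cut-off above
which the worst absolute percentage error stays within 6 %.
"""

from pwvkit import PhantomGridConfig, determine_cutoff, run_phantom_experiment

result = run_phantom_experiment(PhantomGridConfig())
print(f"evaluated {result.n_conditions} phantom conditions\n")
print(result.to_frame().round(2).to_string(index=False))

cutoff = determine_cutoff(result.rows, tolerance_pct=6.0)
cycle = result.config.waveform.cycle_ms
print(f"\ncut-off: {cutoff} frames per cycle "
      f"({cycle / cutoff:.1f} ms temporal resolution): from here on, the "
      f"worst |PWV error| over 2-20 m/s stays within 6 %")

# Reading the table: errors are small at 40 frames, grow as the sampling
# coarsens (the anti-aliasing low-pass increasingly smooths the upstroke,
# flattening the tangents), and fluctuate non-monotonically below ~30
# frames where the fit window straddles too few genuine upslope samples.
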