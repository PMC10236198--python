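"""Fuse two PC-MRI-style flow waveforms and quantify the left/right split.

Two measurement sites along the same draining sinus are averaged into one
inflow boundary condition; the transverse-sinus waveforms are integrated over
the cycle to get the fractional division of venous outflow.
"""
import numpy as np

from venoflow import Waveform, average_waveforms, flow_split, synth_waveform

# two sites along the falcine-sinus analog, 10 cardiac phases each
t = np.arange(10) / 10 * 0.5
site_a = Waveform(t, 8.0 + 1.2 * np.sin(2 * np.pi * t / 0.5), period=0.5)
site_b = Waveform(t, 7.4 + 0.9 * np.sin(2 * np.pi * t / 0.5 + 0.4), period=0.5)

inflow = average_waveforms(site_a, site_b)
print(f"site A cycle mean : {site_a.cycle_mean():.3f} mL/s")
print(f"site B cycle mean : {site_b.cycle_mean():.3f} mL/s")
print(f"fused inflow mean : {inflow.cycle_mean():.3f} mL/s  (the CFD boundary condition)")

# left/right transverse sinus split
left = synth_waveform(4.6, 0.3, period=0.5, seed=2)
right = synth_waveform(3.1, 0.3, period=0.5, seed=3)
split = flow_split(left, right)
print(
    f"\noutflow split     : left {split.fraction_left:.3f} / right "
    f"{split.fraction_right:.3f}"
)
print("Fractions are cycle-integrated and always sum to 1.")
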