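"""Stimulus-side computations: transparency mask, tagging waveform, frame timing.

Run:  python examples/01_stimulus_computations.py
"""

import numpy as np

from riftpipe import synthgen

# The flickering patches are blended into the background with a radial
# sigmoid mask: semi-transparent (0.5) at the center, opaque (~1) at the rim.
r = 3.0  # patch radius, dva
for x in (0.0, r / 2, r):
    print(f"mask T(x={x:.1f}, r={r}) = {synthgen.transparency_mask(x, r):.5f}")

# The tag itself is a luminance sinusoid phase-locked to cue onset.
wave = synthgen.tagging_waveform(60.0, duration=1.0, fs=480.0)
print(f"60 Hz tag at the 480 Hz projector: {len(wave)} frames, "
      f"{np.sum((wave[:-1] <= 0) & (wave[1:] > 0))} cycles in 1 s")

# Trials in which any frame is displayed > 4 ms off-time are excluded.
good = np.arange(100) / 480.0
late = good.copy()
late[50] += 0.005  # one frame 5 ms late
flags = synthgen.flag_offtime_trials([good, late])
print(f"frame-timing exclusion flags: on-time trial -> {flags[0]}, "
      f"5 ms glitch -> {flags[1]}")
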