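"""Adaptive QUEST staircase driving a simulated Weibull observer.

Run:  python examples/03_quest_staircase.py
"""

import numpy as np

from riftpipe import quest

observer = quest.ObserverModel(true_threshold_deg=15.0)  # beta=3.5, delta=0.01, gamma=0.5
session = quest.simulate_session(observer, n_trials=480, seed=1)

print(f"true threshold: {observer.true_threshold_deg:.1f} deg")
print(f"posterior-mean estimate after 480 trials: "
      f"{session.final_state.threshold_estimate_deg:.1f} deg")
print(f"accuracy over the last 300 trials: {session.late_accuracy(300) * 100:.1f} % "
      f"(the staircase targets 75 %)")
print(f"first 5 probe offsets: {np.round(session.intensities[:5], 1)} deg")
print(f"last 5 probe offsets:  {np.round(session.intensities[-5:], 1)} deg")
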