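"""Cluster-based permutation test and bootstrap mean-difference test.

Run:  python examples/04_resampling_statistics.py
"""

import numpy as np

from riftpipe import stats

rng = np.random.default_rng(0)
fs = 250.0
n_participants, n_t = 12, 250  # 1 s traces

# Difference traces with a genuine effect between 0.4 and 0.7 s.
times = np.arange(n_t) / fs
effect = 0.8 * ((times >= 0.4) & (times < 0.7))
X = effect + rng.standard_normal((n_participants, n_t))

res = stats.cluster_permutation_test(X, fs, times=times, n_permutations=2000, seed=1)
print("cluster permutation test (sign-flip null, max |t-mass|):")
for c in res.clusters:
    tag = "SIGNIFICANT" if c.significant else "n.s."
    print(f"  {c.start_s:.3f}-{c.end_s:.3f} s  t-mass={c.t_mass:8.1f}  p={c.p:.4f}  {tag}")

# Bootstrap comparison of two per-participant value sets.
a = rng.normal(0.023, 0.02, size=24)  # e.g. attentional modulation, experiment A
b = rng.normal(0.000, 0.02, size=24)  # experiment B
md = stats.bootstrap_mean_difference(a, b, n_boot=5000, seed=2)
print(f"\nbootstrap mean difference: {md.observed:+.4f}, "
      f"95 % CI [{md.ci_low:+.4f}, {md.ci_high:+.4f}], p={md.p:.4f}")
print("the sets differ" if md.significant else "no difference detected")
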