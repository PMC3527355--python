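"""Design a two-group study: Monte-Carlo power and required sample size.

Estimates power of the two-group comparison over a subjects x reads grid
for a moderate effect, then searches for the smallest per-group cohort
reaching 80% power at alpha = 0.05.
"""

import numpy as np

from dmtaxa import DMParams, effect_size_phi, power_mc, sample_size_search

healthy = DMParams(np.array([0.50, 0.30, 0.20]), 0.02)
disease = DMParams(np.array([0.38, 0.36, 0.26]), 0.02)
print("effect size phi =", round(effect_size_phi([healthy, disease]).phi, 3))

res = power_mc(
    [healthy, disease],
    subjects=[10, 25, 50],
    reads=[500, 2000],
    alpha=0.05,
    n_reps=500,
    seed=3,
)
print("\npower (rows = subjects/group, cols = reads/sample):")
print("          " + "".join(f"{r:>8}" for r in res.reads_grid))
for i, s in enumerate(res.subjects_grid):
    cells = "".join(f"{p:8.3f}" for p in res.power[i])
    print(f"n = {s:4d} {cells}   (+- {res.mc_se[i].max():.3f})")
print("power rises with subjects but is nearly flat in reads: with")
print("overdispersion, extra reads cannot remove between-subject variation.")

size = sample_size_search(
    [healthy, disease], target_power=0.80, alpha=0.05,
    reads=2000, n_reps=500, seed=4,
)
print(f"\nsmallest n/group with power >= 80%: {size.n} "
      f"(power {size.power_at_n:.3f} +- {size.mc_se:.3f})")
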