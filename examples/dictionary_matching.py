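"""Conventional MRF reconstruction: dot-product dictionary matching.

Synthesizes a small (f_s x k_sw) dictionary on a 30-iteration rNOE-encoding
schedule, perturbs a batch of dictionary trajectories with measurement-scale
noise, and reports how often exhaustive inner-product matching recovers the
generating grid point.
"""

import numpy as np

from noemrf import (
    Pool,
    TissueParams,
    build_grid,
    dot_product_match,
    inject_noise,
    synthesize,
)
from noemrf.schedules import generate_rnoe_schedule

tissue = TissueParams(
    3.0, 1.5, (Pool("rnoe", -3.5, 1.0, 1e-3, 0.01, 50.0),), field_tesla=7.0
)
schedule = generate_rnoe_schedule(30, -3.5, (0.0, 4.0), seed=8)
grid = build_grid({
    "f_s": np.linspace(0.005, 0.03, 10),
    "k_sw": np.linspace(10.0, 100.0, 10),
})
raw = synthesize(grid, schedule, tissue)
dictionary = raw.normalize()

rng = np.random.default_rng(0)
idx = rng.integers(0, grid.n_entries, size=500)
for sigma in (0.0, 0.005, 0.02):
    queries = inject_noise(raw.signals[idx], sigma, seed=1)
    result = dot_product_match(dictionary, queries)
    rate = np.mean(result.indices == idx)
    print(f"noise sigma={sigma:<6} exact grid-point recovery: {rate:6.1%} "
          f"(mean match score {result.scores.mean():.5f})")

print()
print("Each query is compared to all 100 normalized dictionary entries; the")
print("best inner product picks the parameter pair. Recovery degrades")
print("gracefully as the added noise grows relative to the signal encoding.")
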