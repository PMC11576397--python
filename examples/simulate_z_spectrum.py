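"""Simulate a CW Z-spectrum of a brain-like three-pool system.

Builds a water + rNOE + semisolid-MT tissue, applies 2 uT continuous-wave
saturation at a sweep of frequency offsets, and prints the steady-ish water
Z value at each offset. The broad dip across all offsets is the semisolid
MT background; the asymmetry around -3.5 ppm is the rNOE contribution.
"""

import numpy as np

from noemrf import (
    Pool,
    SaturationEvent,
    TissueParams,
    equilibrium_state,
    propagate,
)

tissue = TissueParams(
    water_t1_s=1.8,
    water_t2_s=0.04,
    pools=(
        Pool("rnoe", -3.5, 1.0, 1e-3, 0.0149, 67.5),
        Pool("semisolid", 0.0, 1.0, 1e-5, 0.15, 36.0, "super-lorentzian"),
    ),
    field_tesla=7.0,
)

offsets = np.arange(-6.0, 6.5, 1.0)
print("offset_ppm   Z")
for offset in offsets:
    event = SaturationEvent("cw", b1_uT=2.0, duration_s=4.0, offset_ppm=offset)
    state = propagate(equilibrium_state(tissue), tissue, event)
    print(f"{offset:+8.1f}   {state.water_mz:.4f}")

print()
print("Z = saturated water magnetization / equilibrium magnetization.")
print("Note the lower Z at -3.5 ppm than at +3.5 ppm: saturation applied at")
print("the aliphatic proton frequency is relayed to water by the rNOE pool,")
print("on top of the symmetric semisolid-MT and direct-saturation dips.")
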