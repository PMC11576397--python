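"""Single-network quantification of a glycogen vial phantom, end to end.

Simulates a six-vial digital phantom (25-300 mM glucosyl units), trains the
four-layer reconstruction network on a simulated-signal dictionary, infers
concentration and exchange-rate maps, and compares vial means to the known
concentrations. Runs in roughly a minute on one CPU.
"""

from noemrf.experiments import glyco_phantom_experiment

result = glyco_phantom_experiment(seed=1)

print("vial   truth (mM)   estimated (mM)   est. k_sw (1/s)")
for truth, est, k in zip(
    result["truth_mm"], result["estimated_mm"], result["estimated_k_sw"]
):
    print(f"       {truth:8.0f}     {est:10.1f}      {k:10.1f}")

print()
print(f"Pearson r = {result['pearson_r']:.4f} (p = {result['p_value']:.2e}), "
      f"range-NRMSE = {result['nrmse']:.3f}")
print()
print("The concentration estimates track the ground truth linearly while the")
print("exchange-rate estimates stay flat near the shared generating value --")
print("the rate is decoupled from the concentration, as it should be.")
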