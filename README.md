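# noemrf

Quantitative mapping of the relayed nuclear Overhauser effect (rNOE) and
semisolid magnetization transfer (MT) with magnetic resonance
fingerprinting (MRF) and neural-network reconstruction.

## The problem

The rNOE is a molecular MRI contrast from carbon-bound protons of mobile
macromolecules (membrane lipids, proteins, glycogen): selective saturation
applied near −3.5 ppm (brain aliphatic protons) or −1 ppm (glycogen) is
relayed to the water signal through cross-relaxation and exchange.
Conventional rNOE-weighted imaging requires long Z-spectrum acquisitions
and convolves the effect of interest with water T1, direct saturation, and
the much stronger semisolid-MT background — so the weighted signal cannot
be read as a concentration.

This package implements the fingerprinting alternative: a pseudo-random
saturation schedule (30 iterations of varying power, and offset where
useful) encodes each pixel's response as a signal trajectory; trajectories
are compared against (or regressed on) signals simulated from the
Bloch–McConnell equations

dM/dt = A(ω₁, Δω) · M + b,

for a water + rNOE + semisolid-MT pool system, yielding per-pixel estimates
of the proton volume fractions f_ss, f_s and exchange rates k_ssw, k_sw
(s⁻¹). Reconstruction is either conventional dot-product dictionary
matching or a four-layer fully connected network (2 × 300 ReLU units,
sigmoid output) trained purely on simulated dictionaries. For in vivo use a
sequential two-network scheme first pins down the semisolid-MT parameters
from an MT-encoding protocol (6–14 ppm), then feeds them pixel-wise into a
second network together with the rNOE-encoding trajectories (−3.5 ppm) for
more accurate rNOE quantification.

Audience: MRI physicists and methods researchers working on CEST/MT/rNOE
quantification who need a self-contained, scanner-free implementation —
solver, schedules, dictionaries, matching, networks, digital phantoms, and
evaluation statistics.

## Worked example

`examples/vial_phantom_reconstruction.py` simulates a six-vial glycogen
phantom (25–300 mM glucosyl units, measurement noise σ = 0.002), trains the
reconstruction network on a 4,646-entry simulated dictionary, and compares
vial-mean concentration estimates with the truth:

```
vial   truth (mM)   estimated (mM)   est. k_sw (1/s)
             25           34.0            45.1
             50           48.4            49.0
            100           93.5            49.5
            150          146.8            51.2
            200          204.1            51.1
            300          290.9            50.1

Pearson r = 0.9984 (p = 3.94e-06), range-NRMSE = 0.023
```

The estimates track the truth linearly (r > 0.98) and the exchange-rate
estimates stay flat near the shared generating value of 50 s⁻¹ — the rate
is decoupled from the concentration. The other example scripts show the
Z-spectrum of a three-pool brain tissue (`simulate_z_spectrum.py`),
dot-product matching recovery under noise (`dictionary_matching.py`), and
the sequential two-network WM/GM brain mapping
(`sequential_brain_mapping.py`).

A thin CLI mirrors the library for shell use:

```bash
mrf schedule generate --protocol rnoe --offset -3.5 --n 30 --seed 42 -o sched.yaml
mrf phantom make --kind glycogen -o phantom
mrf simulate --phantom phantom --schedule sched.yaml --sigma 0.002 --seed 1 -o stack.nii.gz
mrf dict build --grid grid.yaml --schedule sched.yaml -o dict.h5
mrf train --dict dict.h5 --outputs conc_mm,k_sw --seed 0 -o model.npz
mrf infer --model model.npz --stack stack.nii.gz -o maps/
```

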