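# Methods

## The physical model

The package simulates saturation-transfer MRI signals with the
Bloch–McConnell (BM) equations for a free water pool coupled to up to two
solute proton pools:

* an **rNOE pool** — carbon-bound protons of mobile macromolecules
  (aliphatic protons near −3.5 ppm in brain tissue, glycogen glycoNOE near
  −1 ppm), whose saturation is relayed to water. Its transverse relaxation
  time is on the millisecond scale, so the pool is simulated with full
  transverse dynamics (all three magnetization components).
* a **semisolid MT pool** — immobile macromolecular protons with
  microsecond-scale T2. Transverse coherence is unresolvable at that
  linewidth, so the pool is modeled longitudinal-only with a lineshape-based
  saturation rate (Henkelman formalism):

      W = π · ω₁² · g(Δω),

  where `g` is a Lorentzian or super-Lorentzian absorption lineshape
  evaluated at the saturation offset relative to the pool resonance. The
  super-Lorentzian is the default for in vivo tissue, the Lorentzian for
  aqueous phantoms.

Exchange couples matching magnetization components with forward rate
`k_to_water_s` (pool → water) and the detailed-balance reverse rate
`f · k_to_water_s` (water → pool), where `f` is the pool's proton volume
fraction relative to water. All magnetizations are normalized so that
equilibrium water Mz = 1; a pool's equilibrium Mz is `f`.

Unit conventions: γ/2π = 42.5764 MHz/T; `ω₁ = 2π·γ·B1` with B1 in μT;
`Δω = δ·10⁻⁶·2π·γ·B0` for a shift of δ ppm at B0 tesla.

### Propagation

Saturation blocks are piecewise-constant in B1, so the affine linear ODE
`dM/dt = A·M + b` is solved **exactly** per segment with a single matrix
exponential of the augmented homogeneous system — no step-size error. A
pulse train (e.g. the clinical 13 × 100 ms spin-lock train at 50% duty
cycle) alternates an on-pulse propagator with a free-relaxation gap
propagator; the n-fold repetition uses one matrix power.

### Readout model

A fingerprinting iteration is: saturation block → instantaneous sampling of
water Mz → spoiling of all transverse components → scheduled recovery delay.
Echo formation, TE decay, and excitation trains are not simulated; they
scale each pixel's trajectory by a constant factor which the mandatory
2-norm trajectory normalization removes before matching or inference.

### Analytic steady-state oracle

For a water + one-solute system under CW saturation the package provides the
rotating-frame relaxation approximation

    Z = cos²θ · R1w / R1ρ,
    R1ρ = R1w·cos²θ + R2w·sin²θ + Rex,
    Rex = f·k·ω₁² / (ω₁² + p·q + Δωs²·q/p),   p = R2s + k,  q = R1s + k,

with θ = atan(ω₁/Δω) and Δωs the offset from the solute resonance. It is
used purely as an independent cross-check of the numerical propagator, in
its validity regime (slow exchange, solute shift ≫ ω₁); agreement there is
a few tenths of a percent.

## Acquisition schedules

Two 30-iteration encoding strategies, mirroring standard saturation-transfer
fingerprinting practice:

* **mt-encode** — saturation power and offset both pseudo-random, offsets
  confined to 6–14 ppm where mobile-proton (CEST/NOE) pools do not
  contribute; encodes (f_ss, k_ssw).
* **rnoe-encode** — offset fixed at the rNOE resonance (−3.5 ppm brain,
  −1 ppm glycogen), power pseudo-random in 0–4 μT; encodes the combined
  rNOE + MT response.

The first iteration defaults to B1 = 0 as an unsaturated reference anchor
(configurable off). Default CW block timing: 2.5 s saturation, 1.0 s
recovery; the clinical variant replaces CW with the 13 × 100 ms / 50% duty
train. Schedules serialize to YAML and are identified downstream by a
content hash. A pseudo-random schedule is a *fixed acquisition design*: the
shipped protocols are generated once from fixed seeds, and experiment seeds
drive only noise and training.

## Dictionaries

A dictionary is the Cartesian product of declared parameter axes (row-major
order, so flat index ↔ parameter tuple is `numpy.unravel_index`), with one
BM-simulated trajectory per grid point. Synthesis is deterministic and
worker-count invariant (joblib parallelism). Default in vivo axis ranges:
f_ss ∈ [0.01, 0.25], k_ssw ∈ [5, 100] s⁻¹, f_s ∈ [0.001, 0.03],
k_sw ∈ [5, 150] s⁻¹; water T1/T2 fixed per scenario (mouse 7 T: 1.8 s /
40 ms; human 3 T: 1.3 s / 75 ms; aqueous phantom 7 T: 3.0 s / 1.5 s).

Phantom grids can be declared directly in concentration units: a `conc_mm`
axis converts glucosyl mM to pool fraction as `C·n/111000` (water protons
≈ 111 M, default n = 1 labile proton per glucosyl unit); a `conc_pct` axis
uses a configurable linear coefficient (default 10⁻³ fraction per % w/v).
Grid values stay in concentration units so reconstructed maps read in mM or
% w/v.

Training noise is white Gaussian on the **raw** signal scale, added before
the 2-norm re-normalization (default σ = 0.01; the desk-scale closure
studies use the matched measurement level σ = 0.002). Storage is HDF5
(axes + row-chunked signal matrix + schedule hash).

## Matching

Conventional reconstruction: each measured trajectory is 2-norm normalized
and scored by inner product against every normalized dictionary row;
the argmax wins, ties broken by lowest index. Evaluation is chunked over
dictionary rows (chunk-size invariant) to bound memory.

## Neural-network reconstruction

Architecture: four layers — input, two hidden layers of 300 rectified
linear units, and a sigmoid output layer of width 2. Targets are min-max
scaled to (0,1) over their grid ranges to match the sigmoid; a degenerate
(single-valued) axis maps to 0.5 and inverts back exactly. Training: Adam,
learning rate 5·10⁻⁴ with a step decay every 10 epochs (factor 0.5 by
default), batch size 256, mean-squared-error loss, a seeded 20% validation
split, and early stopping with patience 5 (best validation weights are
restored). The implementation is plain NumPy with hand-written
backpropagation, so a fixed seed gives bit-identical models on one platform.

Two choices that matter at desk scale:

* **Input standardization.** After 2-norm normalization, informative
  trajectory differences are ~10⁻³ of the unit-norm signal level.
  Each input feature is therefore standardized by its training-dictionary
  mean and s.d. (stored on the model, applied identically at inference).
  Without this the regression is so ill-conditioned that the network barely
  trains at the prescribed learning rate.
* **Decay cadence for small dictionaries.** A 10-epoch decay schedule is
  calibrated for production-scale dictionaries (~10⁷ entries ⇒ tens of
  thousands of optimizer steps per epoch). The desk-scale experiments
  (~10⁴ entries ⇒ tens of steps per epoch) use the configurable decay
  factor 0.9 and up to 300 epochs so the total optimization budget is
  comparable. Defaults are unchanged.

An optional augmentation flag redraws input noise each epoch (applied on
the normalized-trajectory scale, before standardization; side-input columns
stay clean). Default off: training uses a single noisy dictionary copy.

**Sequential mode (in vivo).** Network 1 maps the 30-point MT-encoding
trajectory to (f_ss, k_ssw). Network 2 receives the 30-point rNOE-encoding
trajectory concatenated with those two values in scaled (0,1) units
(input width 32) and outputs (f_s, k_sw). Feeding ground-truth side inputs
never degrades stage-2 accuracy relative to stage-1 estimates (tested).
Models persist as an `.npz` checkpoint plus a JSON sidecar (architecture,
scalers, schedule hash); a hash mismatch at inference warns rather than
fails.

## Synthetic data

The generator provides the package's test objects:

* **Vial phantoms** — circular vials on a 64 × 64 grid over a water
  background; glycogen vials (glycoNOE at −1 ppm) carry mM glucosyl
  concentrations, protein vials (rNOE at −3.5 ppm) % w/v. All vials share
  one slow exchange rate (default 50 s⁻¹), reflecting that phantom rNOE
  rates do not vary with concentration.
* **Brain phantoms** — stylized label maps (mouse: 2-D 64 × 64 elliptical
  cortex ring + central WM band; human: the same structure replicated into
  a 16-slice 3-D volume to exercise 3-D I/O). WM/GM classes carry
  literature-mean exchange parameters (mouse WM: f_ss 15.00%,
  k_ssw 36.06 s⁻¹, f_s 1.49%, k_sw 67.51 s⁻¹; GM: 9.20%, 43.55 s⁻¹,
  0.99%, 53.50 s⁻¹; analogous human 3 T values).

Forward simulation computes one BM trajectory per unique tissue (cached —
numerically identical to per-pixel simulation), then adds seeded white
Gaussian noise per pixel and iteration. What the generator deliberately
omits: anatomy, partial-volume mixing, B0/B1 inhomogeneity, coil profiles,
k-space effects, and physiological variability within a tissue class.
Passing closure tests therefore demonstrate the *pipeline's* consistency
(simulator → dictionary → training → reconstruction → statistics) under the
model's own physics, not robustness to real-scanner confounds.

## Validation experiments

* **Vial-phantom closure** — six glycogen vials (25–300 mM), measurement
  noise σ = 0.002, a 101 × 46 (concentration × rate) dictionary with
  matched training noise. Vial-mean concentration estimates vs. truth:
  Pearson r ≥ 0.98 and range-NRMSE ≤ 0.17 are the acceptance bounds; the
  pipeline typically achieves r ≈ 0.998 and NRMSE ≈ 0.03.
* **Sequential brain closure** — both protocol stacks simulated noiselessly
  from the mouse phantom; stage-1 dictionary 40 × 40, stage-2 dictionary
  8 × 8 × 12 × 12, trained on clean signals. All eight WM/GM ROI means
  recover within 10% (typically within 5%), and the WM/GM contrast ordering
  (f_ss, f_s, k_sw higher in WM; k_ssw higher in GM) is reproduced.
* **Noise-recovery contract** — on the shipped in vivo grids with σ = 0.002,
  each parameter's test-set RMSE stays below 10% of its grid range.
* **Solver contract** — exact propagation agrees with an independently
  coded fixed-step RK4 integration (dt = 10⁻⁵ s) at 10⁻⁵ absolute
  tolerance on randomized three-pool systems, and with the analytic
  two-pool steady state within 1%.

## Numerical choices and degenerate inputs

* Super-Lorentzian on-resonance divergence: for |Δω| < 2π·1.5 kHz the
  lineshape is cubic-interpolated through quadrature anchors at
  ±2π·{1.5, 2, 2.5} kHz; values are cached per (T2, Δω).
* The RK4 oracle's own truncation error grows as ω⁵·dt⁴; the randomized
  comparison systems keep saturation offsets at 3–5 ppm and water T2 ≤ 80 ms
  so the oracle error stays well below the 10⁻⁵ tolerance being checked.
* Matching ties break to the lowest dictionary index; zero-norm
  trajectories are rejected with their row index.
* `inject_noise` with σ = 0 returns its input unchanged (identity), so the
  raw/normalized state of the input is preserved.
* Paired t-test: identical groups return (t = 0, p = 1); a constant nonzero
  difference (zero-variance, unbounded t) raises an error rather than
  returning ±inf.
* Maps mark out-of-mask pixels as NaN (serialized as NaN in NIfTI), never
  0.0.

## Known limitations

* The rNOE pool's T2 (default 1 ms) governs the simulated linewidth of the
  rNOE resonance and is configurable but not estimated; multi-pool rNOE
  structure around −3.5 ppm is not modeled.
* No B0/B1 field-map correction; `b0_shift_ppm` exists per tissue but
  defaults to 0.
* The exact per-iteration powers/offsets of the original scanner protocols
  and the exact axis decomposition of production-scale (~1.9·10⁷ entry)
  dictionaries are not public; shipped schedules and grids are structurally
  faithful, fully configurable stand-ins.
* Desk-scale training (~10⁴ entries) leaves a small residual regression
  bias at grid edges; production use should scale the dictionary up and
  revert to the default decay schedule.
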