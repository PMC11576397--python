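"""End-to-end validation experiments at desk scale.

These functions reproduce, fully in silico, the validation studies that
anchor the method: single-network quantification of a glycogen vial phantom
(concentration recovery vs. ground truth) and sequential two-network
semisolid-MT + rNOE mapping of a stylized mouse brain. They are used by the
test suite and the acceptance script, and serve as worked examples of the
full pipeline.

Protocol schedules are generated with fixed seeds: like a real acquisition
protocol, the pseudo-random saturation series is a fixed design, shipped
with the package. The experiment ``seed`` drives measurement noise and
network training.

Problem sizes (dictionary grids of ~5k-10k entries, 64 x 64 phantoms) are
chosen so each experiment completes in minutes on a single CPU while leaving
comfortable resolution for the reconstruction networks.
"""

from __future__ import annotations

import numpy as np

from .analysis import nrmse, pearson_r, roi_summary
from .bloch_mcconnell import Pool, TissueParams
from .deep_reconstruction import (
    TrainingConfig,
    infer,
    sequential_reconstruct,
    train,
)
from .dictionary import (
    WATER_DEFAULTS,
    Dictionary,
    build_grid,
    inject_noise,
    synthesize,
)
from .schedules import generate_mt_schedule, generate_rnoe_schedule
from .synthetic_data import (
    MOUSE_BRAIN_DEFAULTS,
    RNOE_T1_S,
    RNOE_T2_S,
    SEMISOLID_T1_S,
    SEMISOLID_T2_S,
    forward_simulate_stack,
    make_brain_phantom,
    make_vial_phantom,
)

__all__ = [
    "glyco_phantom_experiment",
    "mouse_sequential_experiment",
    "shipped_glyco_schedule",
    "shipped_mouse_mt_schedule",
    "shipped_mouse_rnoe_schedule",
]

#: Fixed design seeds for the shipped acquisition protocols.
_GLYCO_SCHEDULE_SEED = 11
_MOUSE_MT_SCHEDULE_SEED = 21
_MOUSE_RNOE_SCHEDULE_SEED = 22

#: Measured-image noise (s.d. relative to equilibrium signal) for the
#: phantom study; a realistic high-SNR acquisition level.
PHANTOM_NOISE_SIGMA = 0.002

#: Training configuration for desk-scale dictionaries. The learning-rate
#: decay is gentler (factor 0.9) than the production default (0.5) because a
#: ~10^4-entry dictionary yields few optimizer steps per epoch.
def _desk_config(seed: int, max_epochs: int = 300) -> TrainingConfig:
    return TrainingConfig(seed=seed, max_epochs=max_epochs, decay_factor=0.9)


def shipped_glyco_schedule():
    """30-iteration glycoNOE protocol: fixed -1 ppm offset, 0-4 uT powers."""
    return generate_rnoe_schedule(
        30, -1.0, (0.0, 4.0), seed=_GLYCO_SCHEDULE_SEED,
        protocol_label="phantom-glyco",
    )


def shipped_mouse_mt_schedule():
    """30-iteration semisolid-MT protocol: offsets 6-14 ppm, 0-4 uT powers."""
    return generate_mt_schedule(30, seed=_MOUSE_MT_SCHEDULE_SEED)


def shipped_mouse_rnoe_schedule():
    """30-iteration rNOE protocol: fixed -3.5 ppm offset, 0-4 uT powers."""
    return generate_rnoe_schedule(
        30, -3.5, (0.0, 4.0), seed=_MOUSE_RNOE_SCHEDULE_SEED
    )


def glyco_phantom_experiment(
    seed: int = 1,
    concentrations=(25.0, 50.0, 100.0, 150.0, 200.0, 300.0),
    n_conc: int = 101,
    n_k: int = 46,
    noise_sigma: float = PHANTOM_NOISE_SIGMA,
) -> dict:
    """Single-network closure on a six-vial glycogen phantom.

    Simulates the raw 30-image stack, trains the four-layer network on a
    ~10^4-entry (concentration x exchange-rate) dictionary with injected
    training noise, reconstructs concentration maps, and compares vial-mean
    estimates against the known concentrations.

    Returns a dict with ``pearson_r``, ``p_value``, ``nrmse``, per-vial
    estimates and truths, and the exchange-rate estimates.
    """
    rng = np.random.SeedSequence(seed)
    noise_seed, dict_noise_seed, train_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(3)
    )

    schedule = shipped_glyco_schedule()
    phantom = make_vial_phantom("glycogen", concentrations)
    stack = forward_simulate_stack(
        phantom, schedule, noise_sigma=noise_sigma, seed=noise_seed
    )

    base = TissueParams(
        **WATER_DEFAULTS["phantom_7t"],
        pools=(Pool("rnoe", -1.0, RNOE_T1_S, RNOE_T2_S, 0.001, 50.0),),
        field_tesla=7.0,
    )
    grid = build_grid({
        "conc_mm": np.linspace(0.0, 320.0, n_conc),
        "k_sw": np.linspace(10.0, 100.0, n_k),
    })
    dictionary = synthesize(grid, schedule, base)
    noisy = Dictionary(
        dictionary.grid,
        inject_noise(dictionary.signals, noise_sigma, dict_noise_seed),
        True,
        dictionary.schedule_id,
    )
    model = train(noisy, ("conc_mm", "k_sw"), _desk_config(train_seed, 100))

    maps = infer(model, stack, phantom.foreground_mask())
    vials = [l for l, c in phantom.region_values.items() if c > 0]
    est = np.array([
        roi_summary(maps["conc_mm"], phantom.region_mask(l)).mean for l in vials
    ])
    est_k = np.array([
        roi_summary(maps["k_sw"], phantom.region_mask(l)).mean for l in vials
    ])
    truth = np.array([phantom.region_values[l] for l in vials])
    r, p = pearson_r(est, truth)
    return {
        "pearson_r": r,
        "p_value": p,
        "nrmse": nrmse(est, truth),
        "estimated_mm": est,
        "truth_mm": truth,
        "estimated_k_sw": est_k,
        "n_vials": len(vials),
        "dictionary_entries": grid.n_entries,
    }


def mouse_sequential_experiment(
    seed: int = 1,
    noise_sigma: float = 0.0,
    train_noise_sigma: float = 0.0,
) -> dict:
    """Sequential two-network closure on the stylized mouse-brain phantom.

    WM and GM carry literature-mean exchange parameters; both protocol
    stacks are simulated (noiseless by default), the MT network is trained
    on an (f_ss, k_ssw) dictionary and the rNOE network on a four-axis
    dictionary with (f_ss, k_ssw) side inputs, then the two-stage
    reconstruction is compared against the generating values per region.

    Returns per-class estimated/true parameter means and relative errors.
    """
    rng = np.random.SeedSequence(seed)
    (noise_seed_mt, noise_seed_no, d1_seed, d2_seed, t1_seed, t2_seed) = (
        int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(6)
    )

    phantom = make_brain_phantom("mouse")
    sched_mt = shipped_mouse_mt_schedule()
    sched_no = shipped_mouse_rnoe_schedule()
    stack_mt = forward_simulate_stack(phantom, sched_mt, noise_sigma, noise_seed_mt)
    stack_no = forward_simulate_stack(phantom, sched_no, noise_sigma, noise_seed_no)

    base = TissueParams(
        **WATER_DEFAULTS["mouse_7t"],
        pools=(
            Pool("rnoe", -3.5, RNOE_T1_S, RNOE_T2_S, 0.01, 50.0),
            Pool("semisolid", 0.0, SEMISOLID_T1_S, SEMISOLID_T2_S, 0.1, 40.0,
                 "super-lorentzian"),
        ),
        field_tesla=7.0,
    )

    grid_mt = build_grid({
        "f_ss": np.linspace(0.01, 0.25, 40),
        "k_ssw": np.linspace(5.0, 100.0, 40),
    })
    d1 = synthesize(grid_mt, sched_mt, base)
    grid_no = build_grid({
        "f_ss": np.linspace(0.01, 0.25, 8),
        "k_ssw": np.linspace(5.0, 100.0, 8),
        "f_s": np.linspace(0.001, 0.03, 12),
        "k_sw": np.linspace(5.0, 150.0, 12),
    })
    d2 = synthesize(grid_no, sched_no, base)

    def prepared(d, noise_seed):
        if train_noise_sigma > 0:
            return Dictionary(
                d.grid, inject_noise(d.signals, train_noise_sigma, noise_seed),
                True, d.schedule_id,
            )
        return d.normalize()

    model_mt = train(
        prepared(d1, d1_seed), ("f_ss", "k_ssw"), _desk_config(t1_seed)
    )
    model_no = train(
        prepared(d2, d2_seed), ("f_s", "k_sw"), _desk_config(t2_seed),
        side_input_axes=("f_ss", "k_ssw"),
    )

    maps = sequential_reconstruct(
        model_mt, model_no, stack_mt, stack_no, phantom.foreground_mask()
    )
    results = {}
    for cls, label in (("wm", 1), ("gm", 2)):
        truth = MOUSE_BRAIN_DEFAULTS[cls]
        results[cls] = {}
        for param in ("f_ss", "k_ssw", "f_s", "k_sw"):
            est = roi_summary(maps[param], phantom.region_mask(label)).mean
            results[cls][param] = {
                "estimated": est,
                "truth": truth[param],
                "rel_err": (est - truth[param]) / truth[param],
            }
    results["n_pixels"] = int(phantom.foreground_mask().sum())
    results["dictionary_entries"] = (grid_mt.n_entries, grid_no.n_entries)
    return results
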