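"""Network training, scaling, inference, and the sequential reconstruction."""

import numpy as np
import pytest

from noemrf.bloch_mcconnell import Pool, TissueParams
from noemrf.deep_reconstruction import (
    NetworkSpec,
    ParamScaler,
    TrainingConfig,
    infer,
    load_model,
    save_model,
    sequential_reconstruct,
    train,
)
from noemrf.dictionary import Dictionary, build_grid, inject_noise, synthesize
from noemrf.io import ImageStack, default_affine
from noemrf.schedules import generate_mt_schedule, generate_rnoe_schedule


@pytest.fixture(scope="module")
def toy_dictionary():
    """20 x 20 (f_s, k_sw) dictionary on a short schedule; distinct signals."""
    tissue = TissueParams(
        3.0, 1.5, (Pool("rnoe", -3.5, 1.0, 1e-3, 0.01, 50.0),), field_tesla=7.0
    )
    sched = generate_rnoe_schedule(12, -3.5, (0.0, 4.0), seed=2, t_sat_s=1.5,
                                   recovery_s=0.8)
    grid = build_grid({
        "f_s": np.linspace(0.002, 0.03, 20),
        "k_sw": np.linspace(10.0, 100.0, 20),
    })
    return synthesize(grid, sched, tissue).normalize()


@pytest.fixture(scope="module")
def toy_model(toy_dictionary):
    return train(
        toy_dictionary, ("f_s", "k_sw"),
        TrainingConfig(seed=3, max_epochs=150, decay_factor=0.9),
    )


class TestParamScaler:
    def test_round_trip_identity(self):
        s = ParamScaler(("a", "b"), np.array([0.0, 5.0]), np.array([1.0, 150.0]))
        x = np.array([[0.25, 42.0], [0.9, 149.0]])
        np.testing.assert_allclose(s.inverse(s.forward(x)), x, atol=1e-9)

    def test_degenerate_axis_maps_to_half_and_back(self):
        s = ParamScaler(("a",), np.array([2.0]), np.array([2.0]))
        assert s.forward(np.array([[2.0]]))[0, 0] == 0.5
        assert s.inverse(np.array([[0.7]]))[0, 0] == 2.0


class TestTraining:
    def test_toy_recovery_noiseless(self, toy_dictionary, toy_model):
        """Held-out noiseless trajectories map back to their generating
        parameters within 5% of each axis range."""
        rng = np.random.default_rng(7)
        idx = rng.choice(toy_dictionary.grid.n_entries, size=80, replace=False)
        pred = toy_model.predict(toy_dictionary.signals[idx])
        names = toy_dictionary.grid.axis_names
        truth = toy_dictionary.grid.value_matrix()[idx][
            :, [names.index("f_s"), names.index("k_sw")]
        ]
        ranges = np.array([0.03 - 0.002, 100.0 - 10.0])
        mae = np.mean(np.abs(pred - truth), axis=0)
        assert np.all(mae < 0.05 * ranges)

    def test_training_is_deterministic_given_seed(self, toy_dictionary):
        cfg = TrainingConfig(seed=11, max_epochs=5)
        m1 = train(toy_dictionary, ("f_s", "k_sw"), cfg)
        m2 = train(toy_dictionary, ("f_s", "k_sw"), cfg)
        for (w1, b1), (w2, b2) in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
            np.testing.assert_array_equal(b1, b2)

    def test_constant_targets_learned_as_constant(self, toy_dictionary):
        """A degenerate regression with a single-valued output axis converges
        to that constant."""
        sig = toy_dictionary.signals[25][None]
        # 50 near-identical entries so batching and validation have data;
        # k_sw is single-valued (degenerate output axis)
        rep = Dictionary(
            build_grid({"f_s": np.linspace(0.0099, 0.0101, 50), "k_sw": [50.0]}),
            np.tile(sig, (50, 1)), True, "const",
        )
        model = train(rep, ("f_s", "k_sw"), TrainingConfig(seed=1, max_epochs=30))
        pred = model.predict(sig)
        assert pred[0, 0] == pytest.approx(0.01, abs=2e-4)
        assert pred[0, 1] == pytest.approx(50.0, abs=1e-6)

    def test_missing_output_axis_rejected(self, toy_dictionary):
        with pytest.raises(KeyError):
            train(toy_dictionary, ("f_ss", "k_ssw"), TrainingConfig(max_epochs=1))

    def test_unnormalized_dictionary_rejected(self, toy_dictionary):
        raw = Dictionary(toy_dictionary.grid, toy_dictionary.signals, False, "x")
        with pytest.raises(ValueError, match="normalized"):
            train(raw, ("f_s", "k_sw"), TrainingConfig(max_epochs=1))


class TestInference:
    def test_dictionary_row_maps_to_grid_point(self, toy_dictionary, toy_model):
        i = 150
        p = toy_dictionary.grid.point(i)
        pred = toy_model.predict(toy_dictionary.signals[i][None])[0]
        assert pred[0] == pytest.approx(p["f_s"], abs=0.05 * 0.028)
        assert pred[1] == pytest.approx(p["k_sw"], abs=0.05 * 90.0)

    def test_masked_pixels_are_nan_not_zero(self, toy_dictionary, toy_model):
        n = toy_dictionary.signals.shape[1]
        stack = ImageStack(
            np.tile(toy_dictionary.signals[10], (3, 3, 1, 1)).reshape(3, 3, 1, n),
            default_affine(),
        )
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[0, 0, 0] = True
        maps = infer(toy_model, stack, mask)
        assert np.isnan(maps["f_s"][2, 2, 0])
        assert not np.isnan(maps["f_s"][0, 0, 0])

    def test_constant_stack_gives_constant_maps(self, toy_dictionary, toy_model):
        n = toy_dictionary.signals.shape[1]
        stack = ImageStack(
            np.tile(toy_dictionary.signals[42], (4, 5, 1, 1)).reshape(4, 5, 1, n),
            default_affine(),
        )
        maps = infer(toy_model, stack)
        assert np.ptp(maps["f_s"]) == 0.0
        assert np.ptp(maps["k_sw"]) == 0.0

    def test_pixel_permutation_equivariance(self, toy_dictionary, toy_model):
        rng = np.random.default_rng(21)
        idx = rng.integers(0, toy_dictionary.grid.n_entries, size=12)
        n = toy_dictionary.signals.shape[1]
        data = toy_dictionary.signals[idx].reshape(3, 4, 1, n)
        maps = infer(toy_model, ImageStack(data, default_affine()))
        perm = rng.permutation(12)
        data_p = toy_dictionary.signals[idx[perm]].reshape(3, 4, 1, n)
        maps_p = infer(toy_model, ImageStack(data_p, default_affine()))
        np.testing.assert_allclose(
            maps_p["f_s"].ravel(), maps["f_s"].ravel()[perm]
        )

    def test_dimension_mismatch_rejected(self, toy_model):
        stack = ImageStack(np.ones((2, 2, 1, 7)), default_affine())
        with pytest.raises(ValueError):
            infer(toy_model, stack)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, toy_dictionary, toy_model):
        path = tmp_path / "model.npz"
        save_model(toy_model, path)
        loaded = load_model(path)
        x = toy_dictionary.signals[:5]
        np.testing.assert_array_equal(loaded.predict(x), toy_model.predict(x))
        assert loaded.schedule_id == toy_model.schedule_id


@pytest.fixture(scope="module")
def sequential_setup():
    """Small two-protocol setup: MT network + side-informed rNOE network."""
    tissue = TissueParams(
        1.8, 0.04,
        (
            Pool("rnoe", -3.5, 1.0, 1e-3, 0.01, 50.0),
            Pool("semisolid", 0.0, 1.0, 1e-5, 0.1, 40.0, "lorentzian"),
        ),
        field_tesla=7.0,
    )
    sched_mt = generate_mt_schedule(12, seed=31, t_sat_s=1.5, recovery_s=0.8)
    sched_no = generate_rnoe_schedule(12, -3.5, (0, 4), seed=32, t_sat_s=1.5,
                                      recovery_s=0.8)
    g1 = build_grid({
        "f_ss": np.linspace(0.05, 0.2, 12), "k_ssw": np.linspace(20, 60, 12)
    })
    g2 = build_grid({
        "f_ss": np.linspace(0.05, 0.2, 4), "k_ssw": np.linspace(20, 60, 4),
        "f_s": np.linspace(0.004, 0.02, 7), "k_sw": np.linspace(20, 90, 7),
    })
    d1 = synthesize(g1, sched_mt, tissue).normalize()
    d2 = synthesize(g2, sched_no, tissue).normalize()
    m1 = train(d1, ("f_ss", "k_ssw"),
               TrainingConfig(seed=41, max_epochs=150, decay_factor=0.9))
    m2 = train(d2, ("f_s", "k_sw"),
               TrainingConfig(seed=42, max_epochs=150, decay_factor=0.9),
               side_input_axes=("f_ss", "k_ssw"))
    return tissue, sched_mt, sched_no, m1, m2


class TestSequential:
    def test_two_network_input_width(self, sequential_setup):
        *_, m1, m2 = sequential_setup
        assert m1.spec.input_dim == 12
        assert m2.spec.input_dim == 12 + 2

    def test_oracle_side_inputs_not_worse_than_estimates(self, sequential_setup):
        """Feeding ground-truth MT parameters into the second network must
        not degrade the rNOE estimates relative to stage-1 estimates."""
        from noemrf.bloch_mcconnell import simulate_trajectory
        from noemrf.dictionary import apply_params

        tissue, sched_mt, sched_no, m1, m2 = sequential_setup
        rng = np.random.default_rng(5)
        n_test = 40
        truth = np.stack([
            rng.uniform(0.06, 0.19, n_test),   # f_ss
            rng.uniform(22, 58, n_test),       # k_ssw
            rng.uniform(0.005, 0.019, n_test), # f_s
            rng.uniform(25, 85, n_test),       # k_sw
        ], axis=1)
        traj_mt = np.stack([
            simulate_trajectory(apply_params(tissue, dict(
                f_ss=t[0], k_ssw=t[1], f_s=t[2], k_sw=t[3])), sched_mt)
            for t in truth
        ])
        traj_no = np.stack([
            simulate_trajectory(apply_params(tissue, dict(
                f_ss=t[0], k_ssw=t[1], f_s=t[2], k_sw=t[3])), sched_no)
            for t in truth
        ])
        est_mt = m1.predict(traj_mt)
        pred_est = m2.predict(traj_no, m2.side_scaler.forward(est_mt))
        pred_oracle = m2.predict(traj_no, m2.side_scaler.forward(truth[:, :2]))
        err_est = np.mean(np.abs(pred_est - truth[:, 2:]), axis=0)
        err_oracle = np.mean(np.abs(pred_oracle - truth[:, 2:]), axis=0)
        assert np.all(err_oracle <= err_est * 1.05 + 1e-12)

    def test_sequential_returns_four_maps_and_masks(self, sequential_setup):
        from noemrf.bloch_mcconnell import simulate_trajectory

        tissue, sched_mt, sched_no, m1, m2 = sequential_setup
        n = 12
        t_mt = simulate_trajectory(tissue, sched_mt)
        t_no = simulate_trajectory(tissue, sched_no)
        stack_mt = ImageStack(np.tile(t_mt, (4, 4, 1, 1)).reshape(4, 4, 1, n),
                              default_affine())
        stack_no = ImageStack(np.tile(t_no, (4, 4, 1, 1)).reshape(4, 4, 1, n),
                              default_affine())
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[:2] = True
        maps = sequential_reconstruct(m1, m2, stack_mt, stack_no, mask)
        assert set(maps.maps) == {"f_ss", "k_ssw", "f_s", "k_sw"}
        for name in maps.maps:
            assert np.isnan(maps[name][3, 3, 0])
            assert np.isfinite(maps[name][0, 0, 0])

    def test_misaligned_stacks_rejected(self, sequential_setup):
        *_, m1, m2 = sequential_setup
        s1 = ImageStack(np.ones((4, 4, 1, 12)), default_affine())
        s2 = ImageStack(np.ones((5, 4, 1, 12)), default_affine())
        with pytest.raises(ValueError, match="aligned"):
            sequential_reconstruct(m1, m2, s1, s2)


def test_invivo_grid_recovery_nrmse_under_noise():
    """On the shipped in vivo grids with sigma = 0.002 raw-scale noise, each
    recovered parameter's RMSE over a seeded simulated test set stays below
    10% of its grid range."""
    from noemrf.dictionary import WATER_DEFAULTS
    from noemrf.experiments import (
        shipped_mouse_mt_schedule,
        shipped_mouse_rnoe_schedule,
    )
    from noemrf.synthetic_data import (
        RNOE_T1_S,
        RNOE_T2_S,
        SEMISOLID_T1_S,
        SEMISOLID_T2_S,
    )

    base = TissueParams(
        **WATER_DEFAULTS["mouse_7t"],
        pools=(
            Pool("rnoe", -3.5, RNOE_T1_S, RNOE_T2_S, 0.01, 50.0),
            Pool("semisolid", 0.0, SEMISOLID_T1_S, SEMISOLID_T2_S, 0.1, 40.0,
                 "super-lorentzian"),
        ),
        field_tesla=7.0,
    )
    sigma = 0.002
    rng = np.random.default_rng(77)

    # stage 1: semisolid-MT network on the shipped (f_ss, k_ssw) grid
    g1 = build_grid({
        "f_ss": np.linspace(0.01, 0.25, 40),
        "k_ssw": np.linspace(5.0, 100.0, 40),
    })
    d1 = synthesize(g1, shipped_mouse_mt_schedule(), base)
    d1n = Dictionary(d1.grid, inject_noise(d1.signals, sigma, 811), True,
                     d1.schedule_id)
    m1 = train(d1n, ("f_ss", "k_ssw"),
               TrainingConfig(seed=81, max_epochs=300, decay_factor=0.9))
    idx1 = rng.integers(0, g1.n_entries, size=600)
    test1 = inject_noise(d1.signals[idx1], sigma, 812)
    pred1 = m1.predict(test1)
    truth1 = g1.value_matrix()[idx1]
    for j, name in enumerate(g1.axis_names):
        rng_j = np.ptp(g1.axis_values(name))
        rmse = np.sqrt(np.mean((pred1[:, j] - truth1[:, j]) ** 2))
        assert rmse < 0.10 * rng_j, f"stage-1 {name}: {rmse} vs range {rng_j}"

    # stage 2: rNOE network with (f_ss, k_ssw) side inputs on the shipped
    # four-axis grid
    g2 = build_grid({
        "f_ss": np.linspace(0.01, 0.25, 8),
        "k_ssw": np.linspace(5.0, 100.0, 8),
        "f_s": np.linspace(0.001, 0.03, 12),
        "k_sw": np.linspace(5.0, 150.0, 12),
    })
    d2 = synthesize(g2, shipped_mouse_rnoe_schedule(), base)
    d2n = Dictionary(d2.grid, inject_noise(d2.signals, sigma, 821), True,
                     d2.schedule_id)
    m2 = train(d2n, ("f_s", "k_sw"),
               TrainingConfig(seed=82, max_epochs=300, decay_factor=0.9),
               side_input_axes=("f_ss", "k_ssw"))
    idx2 = rng.integers(0, g2.n_entries, size=600)
    test2 = inject_noise(d2.signals[idx2], sigma, 822)
    truth2 = g2.value_matrix()[idx2]
    names2 = g2.axis_names
    side = m2.side_scaler.forward(
        truth2[:, [names2.index("f_ss"), names2.index("k_ssw")]]
    )
    pred2 = m2.predict(test2, side)
    for j, name in enumerate(("f_s", "k_sw")):
        rng_j = np.ptp(g2.axis_values(name))
        rmse = np.sqrt(np.mean((pred2[:, j] - truth2[:, names2.index(name)]) ** 2))
        assert rmse < 0.10 * rng_j, f"stage-2 {name}: {rmse} vs range {rng_j}"
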