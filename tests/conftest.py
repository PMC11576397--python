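import numpy as np
import pytest

from noemrf.bloch_mcconnell import Pool, TissueParams
from noemrf.schedules import generate_rnoe_schedule


@pytest.fixture
def phantom_tissue():
    """Water + one mobile rNOE pool, phantom-like long water relaxation."""
    return TissueParams(
        water_t1_s=3.0,
        water_t2_s=1.5,
        pools=(Pool("rnoe", -3.5, 1.0, 1e-3, 0.01, 50.0),),
        field_tesla=7.0,
    )


@pytest.fixture
def brain_tissue():
    """Water + rNOE + semisolid-MT three-pool system (mouse-brain-like)."""
    return TissueParams(
        water_t1_s=1.8,
        water_t2_s=0.04,
        pools=(
            Pool("rnoe", -3.5, 1.0, 1e-3, 0.0149, 67.51),
            Pool("semisolid", 0.0, 1.0, 1e-5, 0.15, 36.06, "lorentzian"),
        ),
        field_tesla=7.0,
    )


@pytest.fixture
def short_rnoe_schedule():
    """A 10-iteration rNOE-encoding schedule with short blocks (fast tests)."""
    return generate_rnoe_schedule(
        10, -3.5, (0.0, 4.0), seed=5, t_sat_s=1.0, recovery_s=0.5
    )


def batched_rk4(A, b, v0, duration, dt):
    """Fixed-step RK4 for dM/dt = A M + b, batched over systems.

    Used as the independent integration oracle against the matrix-exponential
    propagator. A: (B, n, n), b: (B, n), v0: (B, n).
    """
    n_steps = int(round(duration / dt))
    v = v0.copy()

    def f(v):
        return np.einsum("bij,bj->bi", A, v) + b

    for _ in range(n_steps):
        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return v
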