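"""Multi-pool Bloch-McConnell simulation for saturation-transfer MRF.

The spin system is a free water pool optionally coupled to one or two solute
pools: a mobile relayed-NOE (rNOE) pool, treated with full transverse dynamics
(its T2 is on the millisecond scale), and a semisolid magnetization-transfer
(MT) pool, treated as a longitudinal-only pool whose direct saturation enters
through a spectral absorption lineshape (Henkelman formalism),

    W = pi * omega_1^2 * g(delta_omega),

with ``g`` a Lorentzian or super-Lorentzian absorption lineshape. All
magnetizations are normalized so that the equilibrium water Mz equals 1; a
solute pool with proton volume fraction ``f`` has equilibrium Mz = f.

Propagation is exact for piecewise-constant saturation: for each constant-B1
segment the affine ODE dM/dt = A M + b is solved with a single matrix
exponential of the homogeneous augmented system. Pulsed saturation (spin-lock
trains) alternates on-segments with free relaxation/exchange gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.linalg import expm

__all__ = [
    "GAMMA_HZ_PER_T",
    "Pool",
    "TissueParams",
    "SaturationEvent",
    "MagnetizationState",
    "UnknownLineshapeError",
    "PropagationError",
    "lineshape_absorption",
    "equilibrium_state",
    "propagate",
    "simulate_trajectory",
    "steady_state_z_two_pool",
    "b1_ut_to_rad_s",
    "ppm_to_rad_s",
]

#: Gyromagnetic ratio of the proton, gamma / 2 pi, in Hz per tesla.
GAMMA_HZ_PER_T = 42.5764e6

LINESHAPES = ("full-bloch", "lorentzian", "super-lorentzian")

#: Frequency cutoff (rad/s) below which the super-Lorentzian is interpolated
#: instead of integrated, to avoid the on-resonance singularity.
_SL_CUTOFF_RAD_S = 2.0 * math.pi * 1.5e3
_SL_ANCHORS_HZ = (1.5e3, 2.0e3, 2.5e3)


class UnknownLineshapeError(ValueError):
    """Raised when a lineshape label is not one of the supported kinds."""


class PropagationError(RuntimeError):
    """Raised when the magnetization state contains non-finite entries."""


def b1_ut_to_rad_s(b1_ut: float) -> float:
    """Convert a saturation amplitude in microtesla to omega_1 in rad/s."""
    return 2.0 * math.pi * GAMMA_HZ_PER_T * 1e-6 * b1_ut


def ppm_to_rad_s(delta_ppm: float, field_tesla: float) -> float:
    """Convert a chemical-shift offset in ppm to rad/s at the given field."""
    return 2.0 * math.pi * GAMMA_HZ_PER_T * field_tesla * delta_ppm * 1e-6


@dataclass(frozen=True)
class Pool:
    """A solute proton pool exchanging magnetization with water.

    Parameters
    ----------
    name:
        Label, e.g. ``"rnoe"`` or ``"semisolid"``.
    delta_ppm:
        Chemical shift relative to water (ppm); brain aliphatic rNOE sits near
        -3.5 ppm, glycogen glycoNOE near -1 ppm, semisolid MT at ~0 ppm.
    t1_s, t2_s:
        Longitudinal / transverse relaxation times (s).
    fraction:
        Proton volume fraction relative to water (dimensionless).
    k_to_water_s:
        Exchange (or magnetization-transfer) rate from the pool to water (1/s).
    lineshape:
        ``"full-bloch"`` for mobile pools simulated with all three
        magnetization components; ``"lorentzian"`` or ``"super-lorentzian"``
        for a longitudinal-only semisolid pool.
    """

    name: str
    delta_ppm: float
    t1_s: float
    t2_s: float
    fraction: float
    k_to_water_s: float
    lineshape: str = "full-bloch"

    def __post_init__(self) -> None:
        if self.t1_s <= 0 or self.t2_s <= 0:
            raise ValueError(f"pool {self.name!r}: T1 and T2 must be positive")
        if not 0 <= self.fraction < 1:
            raise ValueError(f"pool {self.name!r}: fraction must be in [0, 1)")
        if self.k_to_water_s < 0:
            raise ValueError(f"pool {self.name!r}: exchange rate must be >= 0")
        if self.lineshape not in LINESHAPES:
            raise UnknownLineshapeError(
                f"pool {self.name!r}: unknown lineshape {self.lineshape!r}; "
                f"expected one of {LINESHAPES}"
            )


@dataclass(frozen=True)
class TissueParams:
    """Water pool plus 0-2 solute pools and the static field strength."""

    water_t1_s: float
    water_t2_s: float
    pools: tuple[Pool, ...] = ()
    b0_shift_ppm: float = 0.0
    field_tesla: float = 7.0

    def __post_init__(self) -> None:
        if self.water_t1_s <= 0 or self.water_t2_s <= 0:
            raise ValueError("water T1 and T2 must be positive")
        if self.field_tesla <= 0:
            raise ValueError("field_tesla must be positive")
        object.__setattr__(self, "pools", tuple(self.pools))
        if sum(p.fraction for p in self.pools) >= 1:
            raise ValueError("sum of pool fractions must be < 1")

    def pool(self, name: str) -> Pool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(f"no pool named {name!r}")

    def replace_pool(self, name: str, **changes) -> "TissueParams":
        """Return a copy with fields of the named pool replaced."""
        new_pools = tuple(
            replace(p, **changes) if p.name == name else p for p in self.pools
        )
        if all(p.name != name for p in self.pools):
            raise KeyError(f"no pool named {name!r}")
        return replace(self, pools=new_pools)

    def to_dict(self) -> dict:
        return {
            "water_t1_s": self.water_t1_s,
            "water_t2_s": self.water_t2_s,
            "b0_shift_ppm": self.b0_shift_ppm,
            "field_tesla": self.field_tesla,
            "pools": [
                {
                    "name": p.name,
                    "delta_ppm": p.delta_ppm,
                    "t1_s": p.t1_s,
                    "t2_s": p.t2_s,
                    "fraction": p.fraction,
                    "k_to_water_s": p.k_to_water_s,
                    "lineshape": p.lineshape,
                }
                for p in self.pools
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueParams":
        pools = tuple(Pool(**p) for p in d.get("pools", []))
        return cls(
            water_t1_s=d["water_t1_s"],
            water_t2_s=d["water_t2_s"],
            pools=pools,
            b0_shift_ppm=d.get("b0_shift_ppm", 0.0),
            field_tesla=d.get("field_tesla", 7.0),
        )


@dataclass(frozen=True)
class SaturationEvent:
    """One saturation block: CW or a rectangular pulse train.

    For a pulse train, ``n_pulses`` pulses of ``pulse_duration_s`` are played
    with inter-pulse gaps set by ``duty_cycle`` (fraction of on-time within a
    pulse repetition); any remaining time up to ``duration_s`` is free
    relaxation. A clinical spin-lock train of 13 x 100 ms at 50% duty cycle is
    ``SaturationEvent("pulse-train", b1, 2.6, offset, 13, 0.1, 0.5)``.
    """

    shape: str
    b1_uT: float
    duration_s: float
    offset_ppm: float
    n_pulses: int | None = None
    pulse_duration_s: float | None = None
    duty_cycle: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("cw", "pulse-train"):
            raise ValueError(f"unknown saturation shape {self.shape!r}")
        if self.b1_uT < 0:
            raise ValueError("b1_uT must be >= 0")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.shape == "pulse-train":
            if not (self.n_pulses and self.pulse_duration_s and self.duty_cycle):
                raise ValueError(
                    "pulse-train requires n_pulses, pulse_duration_s, duty_cycle"
                )
            if not 0 < self.duty_cycle <= 1:
                raise ValueError("duty_cycle must be in (0, 1]")
            total = self.n_pulses * self.pulse_duration_s / self.duty_cycle
            if total > self.duration_s * (1 + 1e-9) + 1e-9:
                raise ValueError(
                    f"pulse train ({total:.4f} s) does not fit in "
                    f"duration_s={self.duration_s}"
                )

    def to_dict(self) -> dict:
        d = {
            "shape": self.shape,
            "b1_uT": self.b1_uT,
            "duration_s": self.duration_s,
            "offset_ppm": self.offset_ppm,
        }
        if self.shape == "pulse-train":
            d.update(
                n_pulses=self.n_pulses,
                pulse_duration_s=self.pulse_duration_s,
                duty_cycle=self.duty_cycle,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SaturationEvent":
        return cls(**d)


@dataclass
class MagnetizationState:
    """State vector of the coupled system plus its component layout.

    ``vector`` holds (Mx, My, Mz) for water and each full-Bloch pool, and Mz
    only for lineshape-approximated pools, in tissue pool order with water
    first. ``labels`` names each component, e.g. ``"water.Mz"``.
    """

    vector: np.ndarray
    labels: tuple[str, ...]

    def __getitem__(self, label: str) -> float:
        return float(self.vector[self.labels.index(label)])

    @property
    def water_mz(self) -> float:
        return self["water.Mz"]

    def zero_transverse(self) -> "MagnetizationState":
        """Model an imaging readout: spoil all transverse magnetization."""
        v = self.vector.copy()
        for i, lab in enumerate(self.labels):
            if lab.endswith(".Mx") or lab.endswith(".My"):
                v[i] = 0.0
        return MagnetizationState(v, self.labels)


def _state_labels(tissue: TissueParams) -> tuple[str, ...]:
    labels = ["water.Mx", "water.My", "water.Mz"]
    for p in tissue.pools:
        if p.lineshape == "full-bloch":
            labels += [f"{p.name}.Mx", f"{p.name}.My", f"{p.name}.Mz"]
        else:
            labels.append(f"{p.name}.Mz")
    return tuple(labels)


def equilibrium_state(tissue: TissueParams) -> MagnetizationState:
    labels = _state_labels(tissue)
    v = np.zeros(len(labels))
    v[labels.index("water.Mz")] = 1.0
    for p in tissue.pools:
        v[labels.index(f"{p.name}.Mz")] = p.fraction
    return MagnetizationState(v, labels)


# ---------------------------------------------------------------------------
# Lineshapes
# ---------------------------------------------------------------------------

def _super_lorentzian_integrand(theta: float, t2_s: float, dw: float) -> float:
    u = 3.0 * math.cos(theta) ** 2 - 1.0
    if u == 0.0:
        return 0.0
    return (
        math.sin(theta)
        * math.sqrt(2.0 / math.pi)
        * (t2_s / abs(u))
        * math.exp(-2.0 * (dw * t2_s / u) ** 2)
    )


_MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))


def _super_lorentzian_quad(t2_s: float, dw: float) -> float:
    val, _ = quad(
        _super_lorentzian_integrand,
        0.0,
        math.pi / 2.0,
        args=(t2_s, abs(dw)),
        points=[_MAGIC_ANGLE],
        limit=200,
    )
    return val


@lru_cache(maxsize=4096)
def _super_lorentzian_cached(t2_s: float, dw: float) -> float:
    if abs(dw) >= _SL_CUTOFF_RAD_S:
        return _super_lorentzian_quad(t2_s, dw)
    # On-resonance divergence: interpolate through anchor points on both
    # sides of the cutoff band (standard practice, mirrors pulseq-CEST).
    anchors_hz = sorted([-f for f in _SL_ANCHORS_HZ] + list(_SL_ANCHORS_HZ))
    xs = [2.0 * math.pi * f for f in anchors_hz]
    ys = [_super_lorentzian_quad(t2_s, x) for x in xs]
    spline = CubicSpline(xs, ys)
    return float(spline(dw))


def lineshape_absorption(lineshape: str, t2_s: float, delta_omega_rad_s: float) -> float:
    """Absorption lineshape value g (units: s) at offset ``delta_omega_rad_s``.

    Lorentzian: ``g = (T2/pi) / (1 + (dw*T2)^2)``. Super-Lorentzian: the
    orientation integral over fiber angles, with a cubic interpolation across
    the near-resonance band |dw| < 2*pi*1.5 kHz where the integral diverges.
    """
    if t2_s <= 0:
        raise ValueError("t2_s must be positive")
    if lineshape == "lorentzian":
        return (t2_s / math.pi) / (1.0 + (delta_omega_rad_s * t2_s) ** 2)
    if lineshape == "super-lorentzian":
        return _super_lorentzian_cached(float(t2_s), float(delta_omega_rad_s))
    raise UnknownLineshapeError(
        f"no absorption lineshape for {lineshape!r}; expected 'lorentzian' "
        "or 'super-lorentzian'"
    )


# ---------------------------------------------------------------------------
# System matrix and propagation
# ---------------------------------------------------------------------------

def system_matrix(
    tissue: TissueParams, omega1_rad_s: float, offset_ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Build (A, b) of the affine Bloch-McConnell ODE dM/dt = A M + b.

    The rotating frame is locked to the saturation frequency; each pool i
    precesses at its residual offset dw_i = (delta_i + b0_shift - offset).
    B1 is applied along x. Exchange couples matching components of water and
    full-Bloch pools, and Mz only for lineshape pools, with detailed-balance
    forward rate k_wi = f_i * k_i.
    """
    labels = _state_labels(tissue)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    A = np.zeros((n, n))
    b = np.zeros(n)

    r1w = 1.0 / tissue.water_t1_s
    r2w = 1.0 / tissue.water_t2_s
    dw_w = ppm_to_rad_s(tissue.b0_shift_ppm - offset_ppm, tissue.field_tesla)

    wx, wy, wz = idx["water.Mx"], idx["water.My"], idx["water.Mz"]
    A[wx, wx] -= r2w
    A[wx, wy] += dw_w
    A[wy, wx] -= dw_w
    A[wy, wy] -= r2w
    A[wy, wz] += omega1_rad_s
    A[wz, wy] -= omega1_rad_s
    A[wz, wz] -= r1w
    b[wz] += r1w  # M0_water = 1

    for p in tissue.pools:
        k = p.k_to_water_s
        kw = p.fraction * k  # water -> pool
        r1 = 1.0 / p.t1_s
        dw = ppm_to_rad_s(
            p.delta_ppm + tissue.b0_shift_ppm - offset_ppm, tissue.field_tesla
        )
        pz = idx[f"{p.name}.Mz"]
        if p.lineshape == "full-bloch":
            r2 = 1.0 / p.t2_s
            px, py = idx[f"{p.name}.Mx"], idx[f"{p.name}.My"]
            A[px, px] -= r2 + k
            A[px, py] += dw
            A[px, wx] += kw
            A[py, px] -= dw
            A[py, py] -= r2 + k
            A[py, pz] += omega1_rad_s
            A[py, wy] += kw
            A[pz, py] -= omega1_rad_s
            A[pz, pz] -= r1 + k
            A[pz, wz] += kw
            b[pz] += r1 * p.fraction
            # back-exchange into water
            A[wx, wx] -= kw
            A[wx, px] += k
            A[wy, wy] -= kw
            A[wy, py] += k
            A[wz, wz] -= kw
            A[wz, pz] += k
        else:
            w_sat = (
                math.pi
                * omega1_rad_s**2
                * lineshape_absorption(p.lineshape, p.t2_s, dw)
                if omega1_rad_s != 0.0
                else 0.0
            )
            A[pz, pz] -= r1 + k + w_sat
            A[pz, wz] += kw
            b[pz] += r1 * p.fraction
            A[wz, wz] -= kw
            A[wz, pz] += k
    return A, b


def _segment_propagator(A: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Exact affine propagator via the augmented homogeneous system."""
    n = A.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = b
    return expm(aug * t)


def _apply(P: np.ndarray, v: np.ndarray) -> np.ndarray:
    return P[:-1, :-1] @ v + P[:-1, -1]


def propagate(
    state: MagnetizationState,
    tissue: TissueParams,
    event: SaturationEvent,
    dt_max_s: float | None = None,
) -> MagnetizationState:
    """Evolve the magnetization through one saturation event.

    Piecewise-constant segments (CW block, each pulse of a train, each gap)
    are solved exactly with one matrix exponential each; ``dt_max_s`` only
    subdivides segments (the result is identical, it exists for callers that
    want intermediate sampling granularity guarantees).
    """
    if not np.all(np.isfinite(state.vector)):
        bad = [l for l, v in zip(state.labels, state.vector) if not np.isfinite(v)]
        raise PropagationError(f"non-finite magnetization components: {bad}")
    if dt_max_s is not None and dt_max_s <= 0:
        raise ValueError("dt_max_s must be positive")

    omega1 = b1_ut_to_rad_s(event.b1_uT)
    v = state.vector.copy()

    def run_segment(v: np.ndarray, om1: float, t: float) -> np.ndarray:
        if t <= 0:
            return v
        A, b = system_matrix(tissue, om1, event.offset_ppm)
        if dt_max_s is None or t <= dt_max_s:
            return _apply(_segment_propagator(A, b, t), v)
        n_sub = int(math.ceil(t / dt_max_s))
        P = _segment_propagator(A, b, t / n_sub)
        for _ in range(n_sub):
            v = _apply(P, v)
        return v

    if event.shape == "cw":
        v = run_segment(v, omega1, event.duration_s)
    else:
        pd = event.pulse_duration_s
        gap = pd * (1.0 / event.duty_cycle - 1.0)
        A_on, b_on = system_matrix(tissue, omega1, event.offset_ppm)
        A_off, b_off = system_matrix(tissue, 0.0, event.offset_ppm)
        P_on = _segment_propagator(A_on, b_on, pd)
        P_off = _segment_propagator(A_off, b_off, gap) if gap > 0 else None
        P_cycle = P_off @ P_on if P_off is not None else P_on
        # n_pulses-1 full (pulse+gap) cycles, then the final pulse; trailing
        # time up to duration_s is free relaxation.
        if event.n_pulses > 1:
            v = _apply(np.linalg.matrix_power(P_cycle, event.n_pulses - 1), v)
        v = _apply(P_on, v)
        elapsed = event.n_pulses * pd + (event.n_pulses - 1) * gap
        rest = event.duration_s - elapsed
        if rest > 1e-12:
            v = run_segment(v, 0.0, rest)
    if not np.all(np.isfinite(v)):
        raise PropagationError("propagation produced non-finite magnetization")
    return MagnetizationState(v, state.labels)


def simulate_trajectory(tissue: TissueParams, schedule) -> np.ndarray:
    """Simulate the raw MRF signal trajectory (water Mz per iteration).

    Each iteration applies its saturation block to the state left by the
    previous iteration, samples the water longitudinal magnetization (the
    readout is modeled as instantaneous sampling), spoils transverse
    components, and relaxes for the scheduled recovery time. The first
    iteration starts from thermal equilibrium. Returned values are normalized
    to the equilibrium water magnetization (so they lie in [-1, 1]).
    """
    events = list(schedule.events())
    if not events:
        raise ValueError("schedule must contain at least one iteration")
    if getattr(schedule, "field_tesla", tissue.field_tesla) != tissue.field_tesla:
        raise ValueError(
            f"schedule field ({schedule.field_tesla} T) does not match tissue "
            f"field ({tissue.field_tesla} T)"
        )
    state = equilibrium_state(tissue)
    signal = np.empty(len(events))

    # Free-recovery propagators depend only on (tissue, offset, duration);
    # cache them across iterations.
    recovery_cache: dict[tuple[float, float], np.ndarray] = {}
    for i, (event, recovery_s) in enumerate(events):
        state = propagate(state, tissue, event)
        signal[i] = state.water_mz
        state = state.zero_transverse()
        if recovery_s > 0:
            key = (event.offset_ppm, recovery_s)
            P = recovery_cache.get(key)
            if P is None:
                A, b = system_matrix(tissue, 0.0, event.offset_ppm)
                P = _segment_propagator(A, b, recovery_s)
                recovery_cache[key] = P
            state = MagnetizationState(_apply(P, state.vector), state.labels)
    return signal


# ---------------------------------------------------------------------------
# Analytic two-pool steady state (R1rho approximation)
# ---------------------------------------------------------------------------

def steady_state_z_two_pool(
    tissue: TissueParams, b1_uT: float, offset_ppm: float
) -> float:
    """Analytic CW steady-state Z value for a water + one-solute system.

    Uses the rotating-frame relaxation approximation
    ``Z = cos^2(theta) * R1w / R1rho`` with
    ``R1rho = R1w cos^2(theta) + R2w sin^2(theta) + Rex`` and an exchange
    term from the solute's own saturation efficiency
    ``Rex = f k w1^2 / (w1^2 + p q + dws^2 q / p)`` where ``p = R2s + k``,
    ``q = R1s + k`` and ``dws`` is the offset from the solute resonance.
    Valid for slow exchange with the solute shift large compared to omega_1.
    Intended as an independent oracle for the numerical propagator.
    """
    if len(tissue.pools) != 1:
        raise ValueError("steady_state_z_two_pool requires exactly one solute pool")
    pool = tissue.pools[0]
    w1 = b1_ut_to_rad_s(b1_uT)
    r1w = 1.0 / tissue.water_t1_s
    r2w = 1.0 / tissue.water_t2_s
    dw_w = ppm_to_rad_s(offset_ppm - tissue.b0_shift_ppm, tissue.field_tesla)
    if w1 == 0.0:
        return 1.0
    theta = math.atan2(w1, dw_w)
    cos2 = math.cos(theta) ** 2
    sin2 = math.sin(theta) ** 2

    dws = ppm_to_rad_s(
        offset_ppm - pool.delta_ppm - tissue.b0_shift_ppm, tissue.field_tesla
    )
    k = pool.k_to_water_s
    q = 1.0 / pool.t1_s + k
    if pool.lineshape == "full-bloch":
        p = 1.0 / pool.t2_s + k
        rex = pool.fraction * k * w1**2 / (w1**2 + p * q + dws**2 * q / p)
    else:
        w_sat = math.pi * w1**2 * lineshape_absorption(pool.lineshape, pool.t2_s, dws)
        rex = pool.fraction * k * w_sat / (w_sat + q)
    r1rho = r1w * cos2 + r2w * sin2 + rex
    return cos2 * r1w / r1rho
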