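"""Simulated-signal dictionaries: parameter grids, synthesis, normalization.

A dictionary pairs a Cartesian parameter grid (over exchange parameters,
water relaxation, or phantom concentrations) with the matrix of MRF signal
trajectories simulated at every grid point. Rows are stored in row-major
order of the declared axes, so grid index <-> parameter tuple is a bijection
via ``numpy.unravel_index``.

Concentration axes are supported directly: a ``conc_mm`` axis (glucosyl
units, mM) or ``conc_pct`` axis (% w/v protein) is converted to the rNOE pool
proton volume fraction by a configurable linear map, while grid values stay
in concentration units — so matching and network outputs report mM / % w/v,
as phantom maps conventionally do.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np
from joblib import Parallel, delayed

from .bloch_mcconnell import TissueParams, simulate_trajectory
from .schedules import MRFSchedule, schedule_hash

__all__ = [
    "ParameterGrid",
    "Dictionary",
    "build_grid",
    "synthesize",
    "l2_normalize",
    "inject_noise",
    "apply_params",
    "glucosyl_mm_to_fraction",
    "protein_pct_to_fraction",
    "DEFAULT_GRID_RANGES",
    "WATER_DEFAULTS",
]

#: Water protons in pure water are ~111 M; one labile/contributing proton per
#: glucosyl unit by default (configurable).
WATER_PROTON_MM = 111_000.0

#: Default in vivo grid ranges bracketing reported WM/GM means.
DEFAULT_GRID_RANGES = {
    "f_ss": (0.01, 0.25),
    "k_ssw": (5.0, 100.0),
    "f_s": (0.001, 0.03),
    "k_sw": (5.0, 150.0),
}

#: Water relaxation defaults per (species/scenario).
WATER_DEFAULTS = {
    "mouse_7t": {"water_t1_s": 1.8, "water_t2_s": 0.040},
    "human_3t": {"water_t1_s": 1.3, "water_t2_s": 0.075},
    "phantom_7t": {"water_t1_s": 3.0, "water_t2_s": 1.5},
}


def glucosyl_mm_to_fraction(conc_mm: float, n_labile_protons: float = 1.0) -> float:
    """Convert a glucosyl-unit concentration (mM) to a proton volume fraction."""
    return conc_mm * n_labile_protons / WATER_PROTON_MM


def protein_pct_to_fraction(conc_pct: float, fraction_per_pct: float = 1e-3) -> float:
    """Convert a protein concentration (% w/v) to an rNOE proton fraction.

    The linear coefficient is configurable; the default (0.1% pool fraction
    per 1% w/v) is a representative order of magnitude for aliphatic protons
    of globular proteins in solution.
    """
    return conc_pct * fraction_per_pct


# Axis name -> how a value modifies the base tissue. Exchange-parameter axes
# address pools by the conventional names "semisolid" and "rnoe".
def _set_pool(tissue: TissueParams, pool: str, **changes) -> TissueParams:
    return tissue.replace_pool(pool, **changes)


_AXIS_APPLIERS: dict[str, Callable[[TissueParams, float], TissueParams]] = {
    "f_ss": lambda t, v: _set_pool(t, "semisolid", fraction=v),
    "k_ssw": lambda t, v: _set_pool(t, "semisolid", k_to_water_s=v),
    "f_s": lambda t, v: _set_pool(t, "rnoe", fraction=v),
    "k_sw": lambda t, v: _set_pool(t, "rnoe", k_to_water_s=v),
    "water_t1_s": lambda t, v: TissueParams(
        v, t.water_t2_s, t.pools, t.b0_shift_ppm, t.field_tesla
    ),
    "water_t2_s": lambda t, v: TissueParams(
        t.water_t1_s, v, t.pools, t.b0_shift_ppm, t.field_tesla
    ),
    "conc_mm": lambda t, v: _set_pool(
        t, "rnoe", fraction=glucosyl_mm_to_fraction(v)
    ),
    "conc_pct": lambda t, v: _set_pool(
        t, "rnoe", fraction=protein_pct_to_fraction(v)
    ),
}


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid over named parameter axes plus fixed parameters."""

    axes: tuple[tuple[str, tuple[float, ...]], ...]
    fixed: dict = field(default_factory=dict)

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(vals) for _, vals in self.axes)

    @property
    def n_entries(self) -> int:
        return int(np.prod(self.shape))

    def axis_values(self, name: str) -> np.ndarray:
        for n, vals in self.axes:
            if n == name:
                return np.asarray(vals)
        raise KeyError(f"no axis named {name!r}")

    def point(self, index: int) -> dict[str, float]:
        """Parameter dict at the flat row-major ``index``."""
        sub = np.unravel_index(index, self.shape)
        d = dict(self.fixed)
        for (name, vals), i in zip(self.axes, sub):
            d[name] = vals[i]
        return d

    def index_of(self, values: Sequence[float]) -> int:
        """Flat index of an exact per-axis value tuple (inverse of point)."""
        sub = []
        for (name, vals), v in zip(self.axes, values):
            arr = np.asarray(vals)
            hits = np.nonzero(arr == v)[0]
            if len(hits) != 1:
                raise KeyError(f"value {v} not on axis {name!r}")
            sub.append(hits[0])
        return int(np.ravel_multi_index(tuple(sub), self.shape))

    def value_matrix(self) -> np.ndarray:
        """(n_entries, n_axes) array of axis values in row-major order."""
        mesh = np.meshgrid(
            *[np.asarray(vals) for _, vals in self.axes], indexing="ij"
        )
        return np.stack([m.ravel() for m in mesh], axis=1)


def build_grid(
    axes: dict[str, Sequence[float]] | Sequence[tuple[str, Sequence[float]]],
    fixed: dict | None = None,
) -> ParameterGrid:
    """Build a parameter grid from ordered axis declarations.

    Axis value lists must be strictly increasing; duplicate axis names are
    rejected. The total entry count is the product of the axis lengths.
    """
    items = list(axes.items()) if isinstance(axes, dict) else list(axes)
    if not items:
        raise ValueError("at least one axis is required")
    seen = set()
    out = []
    for name, vals in items:
        if name in seen:
            raise ValueError(f"duplicate axis name {name!r}")
        seen.add(name)
        arr = np.asarray(vals, dtype=float)
        if arr.ndim != 1 or len(arr) < 1:
            raise ValueError(f"axis {name!r}: values must be a nonempty 1-D list")
        if len(arr) > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError(f"axis {name!r}: values must be strictly increasing")
        out.append((name, tuple(float(v) for v in arr)))
    return ParameterGrid(axes=tuple(out), fixed=dict(fixed or {}))


def apply_params(base_tissue: TissueParams, params: dict[str, float]) -> TissueParams:
    """Return ``base_tissue`` with grid-point parameters applied."""
    tissue = base_tissue
    for name, value in params.items():
        try:
            applier = _AXIS_APPLIERS[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter axis {name!r}; known: "
                f"{sorted(_AXIS_APPLIERS)}"
            ) from None
        tissue = applier(tissue, value)
    return tissue


@dataclass
class Dictionary:
    """Parameter grid + matrix of simulated trajectories (entries x N)."""

    grid: ParameterGrid
    signals: np.ndarray
    normalized: bool
    schedule_id: str

    def normalize(self) -> "Dictionary":
        if self.normalized:
            return self
        return Dictionary(self.grid, l2_normalize(self.signals), True, self.schedule_id)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["normalized"] = self.normalized
            f.attrs["schedule_id"] = self.schedule_id
            f.attrs["axis_names"] = list(self.grid.axis_names)
            f.create_dataset(
                "signals", data=self.signals, chunks=(min(4096, len(self.signals)),
                self.signals.shape[1]),
            )
            g = f.create_group("axes")
            for name, vals in self.grid.axes:
                g.create_dataset(name, data=np.asarray(vals))
            fx = f.create_group("fixed")
            for k, v in self.grid.fixed.items():
                fx.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        with h5py.File(path, "r") as f:
            names = [str(n) for n in f.attrs["axis_names"]]
            axes = tuple(
                (n, tuple(float(v) for v in f["axes"][n][()])) for n in names
            )
            fixed = {k: f["fixed"].attrs[k] for k in f["fixed"].attrs}
            return cls(
                grid=ParameterGrid(axes=axes, fixed=fixed),
                signals=f["signals"][()],
                normalized=bool(f.attrs["normalized"]),
                schedule_id=str(f.attrs["schedule_id"]),
            )


def _simulate_rows(
    grid: ParameterGrid, schedule: MRFSchedule, base_tissue: TissueParams,
    indices: np.ndarray,
) -> np.ndarray:
    out = np.empty((len(indices), schedule.n_iterations))
    for j, i in enumerate(indices):
        tissue = apply_params(base_tissue, grid.point(int(i)))
        out[j] = simulate_trajectory(tissue, schedule)
    return out


def synthesize(
    grid: ParameterGrid,
    schedule: MRFSchedule,
    base_tissue: TissueParams,
    n_workers: int = 1,
) -> Dictionary:
    """Simulate one trajectory per grid point (deterministic, worker-count
    invariant)."""
    n = grid.n_entries
    indices = np.arange(n)
    if n_workers <= 1 or n < 2 * n_workers:
        signals = _simulate_rows(grid, schedule, base_tissue, indices)
    else:
        chunks = np.array_split(indices, n_workers * 4)
        parts = Parallel(n_jobs=n_workers)(
            delayed(_simulate_rows)(grid, schedule, base_tissue, c)
            for c in chunks
        )
        signals = np.vstack(parts)
    if not np.all(np.isfinite(signals)):
        bad = np.nonzero(~np.isfinite(signals).all(axis=1))[0]
        raise RuntimeError(f"non-finite trajectories at grid entries {bad[:10]}")
    return Dictionary(
        grid=grid, signals=signals, normalized=False,
        schedule_id=schedule_hash(schedule),
    )


def l2_normalize(signals: np.ndarray) -> np.ndarray:
    """Divide each row (trajectory) by its Euclidean norm."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    norms = np.linalg.norm(signals, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if len(zero):
        raise ValueError(f"zero-norm rows at indices {zero[:10].tolist()}")
    return signals / norms[:, None]


def inject_noise(
    signals: np.ndarray, sigma: float, seed: int, renormalize: bool = True
) -> np.ndarray:
    """Add i.i.d. Gaussian noise N(0, sigma^2) to raw trajectories.

    Noise is applied on the raw (pre-normalization) scale; the result is
    2-norm re-normalized by default, ready for matching or training.
    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(seed)
    noisy = signals + rng.normal(0.0, sigma, size=signals.shape)
    return l2_normalize(noisy) if renormalize else noisy
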