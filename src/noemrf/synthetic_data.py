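"""Digital phantoms and in-silico MRF acquisition.

Provides tissue-mimicking objects analogous to the experimental validation
targets of saturation-transfer fingerprinting studies:

* vial phantoms — circular vials of glycogen (glycoNOE at -1 ppm, glucosyl
  concentrations in mM) or protein (BSA-like, rNOE at -3.5 ppm, % w/v)
  surrounded by water;
* stylized mouse (2-D, 64 x 64) and human (small 3-D) brain label maps with
  white-matter / gray-matter / background classes carrying full four-parameter
  (f_ss, k_ssw, f_s, k_sw) tissue descriptions.

``forward_simulate_stack`` turns a phantom plus a schedule into a raw 4-D
image stack by per-pixel Bloch-McConnell simulation (cached per unique
tissue) with optional seeded Gaussian noise, so every downstream stage is
testable without scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .bloch_mcconnell import Pool, TissueParams, simulate_trajectory
from .dictionary import (
    WATER_DEFAULTS,
    glucosyl_mm_to_fraction,
    protein_pct_to_fraction,
)
from .io import ImageStack, default_affine
from .schedules import MRFSchedule, schedule_hash

__all__ = [
    "PhantomSpec",
    "make_vial_phantom",
    "make_brain_phantom",
    "forward_simulate_stack",
    "save_phantom",
    "load_phantom",
    "MOUSE_BRAIN_DEFAULTS",
    "HUMAN_BRAIN_DEFAULTS",
]

#: In vivo WM/GM exchange-parameter means used as phantom ground truth
#: (mouse brain at 7 T; human brain at 3 T).
MOUSE_BRAIN_DEFAULTS = {
    "wm": {"f_ss": 0.1500, "k_ssw": 36.06, "f_s": 0.0149, "k_sw": 67.51},
    "gm": {"f_ss": 0.0920, "k_ssw": 43.55, "f_s": 0.0099, "k_sw": 53.50},
}
HUMAN_BRAIN_DEFAULTS = {
    "wm": {"f_ss": 0.1128, "k_ssw": 22.20, "f_s": 0.0143, "k_sw": 41.46},
    "gm": {"f_ss": 0.0544, "k_ssw": 29.19, "f_s": 0.0115, "k_sw": 37.46},
}

#: Default rNOE pool relaxation (mobile macromolecular protons).
RNOE_T1_S = 1.0
RNOE_T2_S = 1e-3
#: Default semisolid pool relaxation (microsecond-scale T2).
SEMISOLID_T1_S = 1.0
SEMISOLID_T2_S = 1e-5


@dataclass
class PhantomSpec:
    """Labeled digital phantom: region map + per-region tissue parameters.

    ``label_map`` is an integer volume (0 = background); ``region_tissues``
    maps labels to :class:`TissueParams`; ``region_values`` optionally maps
    labels to a scalar ground truth (e.g., concentration in mM).
    """

    label_map: np.ndarray
    region_tissues: dict[int, TissueParams]
    region_values: dict[int, float] = field(default_factory=dict)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim == 2:
            self.label_map = self.label_map[:, :, None]
        missing = set(np.unique(self.label_map)) - {0} - set(self.region_tissues)
        if missing:
            raise ValueError(f"labels without tissue parameters: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_map.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.label_map == label

    def foreground_mask(self) -> np.ndarray:
        return self.label_map > 0


def _vial_centers(n: int, matrix: int, radius_px: float) -> list[tuple[float, float]]:
    """Place n vial centers on a ring (plus one central vial for n >= 7)."""
    if n == 1:
        return [(matrix / 2, matrix / 2)]
    centers = []
    ring_n = min(n, 6)
    ring_r = matrix / 2 - radius_px - 2
    for i in range(ring_n):
        ang = 2 * np.pi * i / ring_n
        centers.append(
            (matrix / 2 + ring_r * np.cos(ang),
             matrix / 2 + ring_r * np.sin(ang))
        )
    for _ in range(n - ring_n):
        centers.append((matrix / 2, matrix / 2))
    return centers


def make_vial_phantom(
    kind: str,
    concentrations,
    matrix: int = 64,
    vial_radius_px: float = 5.0,
    k_exchange_s: float = 50.0,
    water: dict | None = None,
    field_tesla: float = 7.0,
    rnoe_t2_s: float = RNOE_T2_S,
) -> PhantomSpec:
    """Circular-vial phantom: ``kind`` is ``"glycogen"`` (mM glucosyl units,
    glycoNOE at -1 ppm) or ``"bsa"`` (% w/v, rNOE at -3.5 ppm).

    All vials share one exchange rate (phantom rNOE rates sit in the slow
    exchange regime independent of concentration); the background is water.
    """
    if kind not in ("glycogen", "bsa"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    concentrations = list(concentrations)
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    water = dict(WATER_DEFAULTS["phantom_7t"], **(water or {}))
    delta_ppm = -1.0 if kind == "glycogen" else -3.5
    to_fraction = (
        glucosyl_mm_to_fraction if kind == "glycogen" else protein_pct_to_fraction
    )

    centers = _vial_centers(len(concentrations), matrix, vial_radius_px)
    yy, xx = np.mgrid[0:matrix, 0:matrix]
    label_map = np.zeros((matrix, matrix), dtype=int)
    tissues: dict[int, TissueParams] = {}
    values: dict[int, float] = {}
    for i, (conc, (cy, cx)) in enumerate(zip(concentrations, centers), start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= vial_radius_px**2
        if (label_map[disc] != 0).any():
            raise ValueError(f"vial {i} overlaps a previously placed vial")
        label_map[disc] = i
        fraction = to_fraction(conc)
        pools = ()
        if fraction > 0:
            pools = (
                Pool("rnoe", delta_ppm, RNOE_T1_S, rnoe_t2_s, fraction,
                     k_exchange_s, "full-bloch"),
            )
        tissues[i] = TissueParams(
            water["water_t1_s"], water["water_t2_s"], pools,
            field_tesla=field_tesla,
        )
        values[i] = float(conc)
    # background = surrounding water
    bg_label = len(concentrations) + 1
    label_map[label_map == 0] = bg_label
    tissues[bg_label] = TissueParams(
        water["water_t1_s"], water["water_t2_s"], (), field_tesla=field_tesla
    )
    values[bg_label] = 0.0
    return PhantomSpec(label_map, tissues, values)


def _brain_tissue(
    params: dict, water: dict, field_tesla: float, mt_lineshape: str
) -> TissueParams:
    pools = (
        Pool("rnoe", -3.5, RNOE_T1_S, RNOE_T2_S, params["f_s"],
             params["k_sw"], "full-bloch"),
        Pool("semisolid", 0.0, SEMISOLID_T1_S, SEMISOLID_T2_S, params["f_ss"],
             params["k_ssw"], mt_lineshape),
    )
    return TissueParams(
        water["water_t1_s"], water["water_t2_s"], pools, field_tesla=field_tesla
    )


def make_brain_phantom(
    species: str = "mouse",
    parameter_table: dict | None = None,
    mt_lineshape: str = "super-lorentzian",
) -> PhantomSpec:
    """Stylized WM/GM brain phantom with attached exchange parameters.

    Mouse: 2-D 64 x 64 slice — elliptical cortex (GM) ring around a central
    white-matter band (label 1 = WM, 2 = GM). Human: a small 3-D volume
    (16 x 64 x 64 as z x y x x, stored x, y, z) with the same structure per
    slice, exercising 3-D I/O at desk scale. The parameter table must give
    f_ss, k_ssw, f_s, k_sw per class.
    """
    if species == "mouse":
        table = parameter_table or MOUSE_BRAIN_DEFAULTS
        water = WATER_DEFAULTS["mouse_7t"]
        field_tesla = 7.0
        nz = 1
    elif species == "human":
        table = parameter_table or HUMAN_BRAIN_DEFAULTS
        water = WATER_DEFAULTS["human_3t"]
        field_tesla = 3.0
        nz = 16
    else:
        raise ValueError(f"unknown species {species!r}")
    for cls in ("wm", "gm"):
        if cls not in table:
            raise ValueError(f"parameter_table missing class {cls!r}")
        missing = {"f_ss", "k_ssw", "f_s", "k_sw"} - set(table[cls])
        if missing:
            raise ValueError(f"class {cls!r} missing parameters {sorted(missing)}")

    matrix = 64
    yy, xx = np.mgrid[0:matrix, 0:matrix]
    cy = cx = matrix / 2 - 0.5
    outer = ((yy - cy) / 26) ** 2 + ((xx - cx) / 22) ** 2 <= 1.0
    inner = ((yy - cy) / 18) ** 2 + ((xx - cx) / 14) ** 2 <= 1.0
    wm_band = inner & (np.abs(yy - cy) <= 6)
    slice_map = np.zeros((matrix, matrix), dtype=int)
    slice_map[outer] = 2  # cortex / GM
    slice_map[wm_band] = 1  # corpus-callosum-like WM band
    label_map = np.repeat(slice_map[:, :, None], nz, axis=2)

    tissues = {
        1: _brain_tissue(table["wm"], water, field_tesla, mt_lineshape),
        2: _brain_tissue(table["gm"], water, field_tesla, mt_lineshape),
    }
    return PhantomSpec(label_map, tissues)


def forward_simulate_stack(
    phantom: PhantomSpec,
    schedule: MRFSchedule,
    noise_sigma: float = 0.0,
    seed: int = 0,
    cache_tissues: bool = True,
) -> ImageStack:
    """Forward-simulate the raw MRF image stack for a phantom.

    Each pixel's trajectory comes from the Bloch-McConnell simulator for its
    region's tissue (simulated once per unique tissue when caching is on,
    which changes nothing numerically); seeded white Gaussian noise of s.d.
    ``noise_sigma`` (relative to equilibrium water signal) is then added
    independently per pixel and iteration.
    """
    shape = phantom.shape
    n = schedule.n_iterations
    data = np.zeros(shape + (n,))
    cache: dict[int, np.ndarray] = {}
    for label, tissue in phantom.region_tissues.items():
        mask = phantom.region_mask(label)
        if not mask.any():
            continue
        if cache_tissues and label in cache:
            traj = cache[label]
        else:
            traj = simulate_trajectory(tissue, schedule)
            if cache_tissues:
                cache[label] = traj
        data[mask] = traj
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return ImageStack(
        data=data,
        affine=default_affine(phantom.spacing_mm),
        schedule_hash=schedule_hash(schedule),
    )


def save_phantom(phantom: PhantomSpec, path: str | Path) -> None:
    """Write a phantom as ``<path>.yaml`` + ``<path>_labels.nii.gz``."""
    path = Path(path)
    label_path = path.with_name(path.stem + "_labels.nii.gz")
    nib.save(
        nib.Nifti1Image(
            phantom.label_map.astype(np.int16), default_affine(phantom.spacing_mm)
        ),
        str(label_path),
    )
    doc = {
        "label_map": label_path.name,
        "spacing_mm": list(phantom.spacing_mm),
        "regions": {
            int(lbl): {
                "tissue": t.to_dict(),
                "value": phantom.region_values.get(lbl),
            }
            for lbl, t in phantom.region_tissues.items()
        },
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(doc, sort_keys=False))


def load_phantom(path: str | Path) -> PhantomSpec:
    path = Path(path).with_suffix(".yaml")
    doc = yaml.safe_load(path.read_text())
    label_map = np.asarray(
        nib.load(str(path.parent / doc["label_map"])).dataobj
    ).astype(int)
    tissues, values = {}, {}
    for lbl, entry in doc["regions"].items():
        tissues[int(lbl)] = TissueParams.from_dict(entry["tissue"])
        if entry.get("value") is not None:
            values[int(lbl)] = float(entry["value"])
    return PhantomSpec(
        label_map, tissues, values, tuple(doc.get("spacing_mm", (1, 1, 1)))
    )
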