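"""NIfTI image-stack and quantitative-map containers and readers/writers.

An :class:`ImageStack` is a 4-D (x, y, z, iteration) array of raw
MRF-encoded images; 2-D single-slice acquisitions are carried with z = 1.
A :class:`QuantMaps` bundles named parameter volumes (f_ss, k_ssw, f_s,
k_sw, or concentration maps) sharing one geometry, with NaN marking pixels
outside the reconstruction mask. The NIfTI affine is the single source of
spatial truth; voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageStack", "QuantMaps", "read_stack", "write_stack", "write_maps",
           "read_maps"]


@dataclass
class ImageStack:
    """4-D raw MRF image stack with geometry and schedule provenance."""

    data: np.ndarray  # (x, y, z, n_iterations)
    affine: np.ndarray
    schedule_hash: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:  # (x, y, n) single slice
            self.data = self.data[:, :, None, :]
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D stack, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_iterations(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def trajectories(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flatten to (n_pixels, N); optionally restricted to a mask."""
        flat = self.data.reshape(-1, self.n_iterations)
        if mask is None:
            return flat
        return flat[np.asarray(mask, dtype=bool).reshape(-1)]


@dataclass
class QuantMaps:
    """Named quantitative parameter volumes on a shared geometry."""

    maps: dict[str, np.ndarray]
    affine: np.ndarray
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"map volumes disagree in shape: {shapes}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def default_affine(spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def read_stack(path: str | Path, schedule=None) -> ImageStack:
    """Read a NIfTI MRF stack; verify iteration count against a schedule."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, None, :]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 3-D or 4-D NIfTI, got {data.ndim}-D")
    if schedule is not None and data.shape[3] != schedule.n_iterations:
        raise ValueError(
            f"{path}: stack has {data.shape[3]} volumes but the schedule has "
            f"{schedule.n_iterations} iterations"
        )
    return ImageStack(data=data, affine=img.affine)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(stack.data, stack.affine), str(path))


def write_maps(maps: QuantMaps, out_dir: str | Path) -> list[Path]:
    """Write each named map as ``<name>.nii.gz``; NaN marks masked-out pixels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in maps.maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=float), maps.affine), str(p))
        written.append(p)
    if maps.mask is not None:
        p = out_dir / "mask.nii.gz"
        nib.save(
            nib.Nifti1Image(maps.mask.astype(np.uint8), maps.affine), str(p)
        )
        written.append(p)
    return written


def read_maps(map_dir: str | Path) -> QuantMaps:
    map_dir = Path(map_dir)
    maps, affine, mask = {}, None, None
    for p in sorted(map_dir.glob("*.nii.gz")):
        img = nib.load(str(p))
        name = p.name.removesuffix(".nii.gz")
        if name == "mask":
            mask = np.asarray(img.dataobj).astype(bool)
        else:
            maps[name] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    if not maps:
        raise FileNotFoundError(f"no map volumes found in {map_dir}")
    return QuantMaps(maps=maps, affine=affine, mask=mask)
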