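"""3-D voxel volumes: the pipeline's imaging currency.

Axis convention (fixed throughout the package):

* axis 0, ``z`` — axial slice, superior → inferior
* axis 1, ``y`` — anterior → posterior
* axis 2, ``x`` — patient-right → patient-left

World coordinates are ``index * spacing_mm`` (0-based indices, no origin
offset). Volumes round-trip through NIfTI via nibabel; the on-disk array keeps
the in-memory (z, y, x) axis order with a diagonal affine carrying the voxel
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import ParameterError, ShapeError

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3-D scalar grid (CT-like units or perfusion counts) with voxel spacing."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (3.9, 3.9, 3.9)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ShapeError(f"volume must be 3-D, got ndim={self.values.ndim}")
        if any(n < 1 for n in self.values.shape):
            raise ShapeError(f"volume shape must be >=1 per axis, got {self.values.shape}")
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing_mm).ravel())
        if len(spacing) == 1:
            spacing = spacing * 3
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        self.spacing_mm = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        sz, sy, sx = self.spacing_mm
        return sz * sy * sx / 1000.0

    def same_grid_as(self, other: "VoxelVolume | np.ndarray") -> bool:
        other_shape = other.shape if isinstance(other, np.ndarray) else other.values.shape
        return tuple(self.values.shape) == tuple(other_shape)

    def save_nifti(self, path) -> None:
        sz, sy, sx = self.spacing_mm
        affine = np.diag([sz, sy, sx, 1.0])
        img = nib.Nifti1Image(np.asarray(self.values), affine)
        img.header.set_zooms((sz, sy, sx))
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path) -> "VoxelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        return cls(values=np.asarray(data), spacing_mm=tuple(float(z) for z in zooms))


def require_same_grid(a: np.ndarray, b: np.ndarray, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise ShapeError(f"{what} must share a grid: {a.shape} vs {b.shape}")
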