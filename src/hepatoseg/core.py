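"""Common volumetric containers and NIfTI I/O.

A :class:`Volume` is a 3D scalar intensity grid with physical voxel spacing;
a :class:`Mask` is a label grid on the same geometry.  Axis order is (x, y, z)
throughout the package, and ``spacing`` is millimetres per voxel along each
axis.  NIfTI round-trips preserve spacing in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# label conventions shared by phantoms, segmentation and metrics
BACKGROUND = 0
LIVER = 1
LESION = 2
VESSEL = 3


@dataclass
class Volume:
    """3D scalar intensity grid with anisotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class Mask:
    """Label grid aligned to a :class:`Volume` (0 bg, 1 liver, 2 lesion, 3 vessel)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype == bool:
            self.data = self.data.astype(np.uint8)
        self.data = self.data.astype(np.uint8, copy=False)
        if self.data.ndim != 3:
            raise ValueError(f"Mask must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean array for one label, or for any foreground if label is None."""
        if label is None:
            return self.data > 0
        return self.data == label

    def volume_ml(self, label: int | None = None) -> float:
        return float(self.binary(label).sum()) * float(np.prod(self.spacing)) / 1000.0


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_volume(vol: Volume | Mask, path: str) -> None:
    """Write a volume or mask as NIfTI with spacing in the affine."""
    img = nib.Nifti1Image(np.asarray(vol.data), _affine_from_spacing(vol.spacing))
    nib.save(img, path)


def read_volume(path: str) -> Volume:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.dataobj, dtype=np.float64), spacing)


def read_mask(path: str) -> Mask:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask(np.asarray(img.dataobj).astype(np.uint8), spacing)
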