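"""3-D MR contrast volumes and NIfTI round-trip.

A :class:`ContrastVolume` is the package-wide container for one contrast of
one dataset: a real-valued voxel array, its voxel spacing in millimetres, a
contrast label, and the index of the sagittal axis along which slice-wise
training and synthesis operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Recognised contrast labels.
CONTRASTS = ("T1", "T2", "T2FS", "SYNTH_T2FS")


@dataclass
class ContrastVolume:
    """One 3-D MR contrast.

    Parameters
    ----------
    data
        Voxel intensities, 3-D float array.
    spacing
        Millimetres per voxel along each array axis.
    contrast
        One of :data:`CONTRASTS`.
    slice_axis
        Array axis indexing sagittal slices (default 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    contrast: str
    slice_axis: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}; expected one of {CONTRASTS}")
        if not 0 <= self.slice_axis < 3:
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def inplane_spacing(self) -> tuple[float, float]:
        axes = [a for a in range(3) if a != self.slice_axis]
        return (self.spacing[axes[0]], self.spacing[axes[1]])

    def slices(self) -> np.ndarray:
        """View with the sagittal axis first, shape (n_slices, H, W)."""
        return np.moveaxis(self.data, self.slice_axis, 0)

    def with_data(self, data: np.ndarray, contrast: str | None = None) -> "ContrastVolume":
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       contrast=contrast or self.contrast)

    # -- NIfTI round trip ---------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.spacing)
        img.header["descrip"] = f"spinefs:{self.contrast}:axis{self.slice_axis}".encode()
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, contrast: str | None = None,
             slice_axis: int = 0) -> "ContrastVolume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if contrast is None:
            descrip = bytes(img.header["descrip"]).decode(errors="ignore")
            if descrip.startswith("spinefs:"):
                parts = descrip.split(":")
                contrast = parts[1]
                if len(parts) > 2 and parts[2].startswith("axis"):
                    slice_axis = int(parts[2][4])
            else:
                raise ValueError("contrast label missing: pass contrast= explicitly")
        return cls(data=data, spacing=spacing, contrast=contrast, slice_axis=slice_axis)
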