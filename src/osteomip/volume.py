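"""Radiodensity volumes and their file I/O (NIfTI, DICOM series)."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = ["DensityVolume", "read_volume", "write_nifti"]


@dataclass
class DensityVolume:
    """A 3D radiodensity grid with voxel spacing.

    values : 3D array, abstract radiodensity or HU
    spacing : mm per axis, same axis order as ``values``
    projection_axis : grid axis along the line of sight (distal -> proximal)
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    projection_axis: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.projection_axis not in (0, 1, 2):
            raise ValueError("projection_axis must be 0, 1 or 2")

    def oriented(self) -> "DensityVolume":
        """Return a copy with the projection axis moved to axis 0."""
        if self.projection_axis == 0:
            return self
        values = np.moveaxis(self.values, self.projection_axis, 0)
        sp = list(self.spacing)
        sp.insert(0, sp.pop(self.projection_axis))
        return DensityVolume(values=values, spacing=tuple(sp), projection_axis=0)


def write_nifti(volume: DensityVolume, path: str) -> None:
    """Write a volume as NIfTI with spacing in the affine diagonal."""
    import nibabel as nib

    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    nib.save(img, path)


def _read_dicom_series(directory: str) -> DensityVolume:
    import pydicom

    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.lower().endswith(".dcm")
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(getattr(s, "SliceLocation", s.InstanceNumber)))
    values = np.stack([s.pixel_array.astype(float) for s in slices], axis=0)
    first = slices[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    values = values * slope + intercept
    dz = float(getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 1.0)))
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    return DensityVolume(values=values, spacing=(dz, dy, dx), projection_axis=0)


def read_volume(path: str, projection_axis: int = 0) -> DensityVolume:
    """Read a NIfTI file or a DICOM series directory into a DensityVolume."""
    if os.path.isdir(path):
        vol = _read_dicom_series(path)
        vol.projection_axis = projection_axis
        return vol
    import nibabel as nib

    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DensityVolume(
        values=np.asarray(img.dataobj, dtype=float),
        spacing=spacing,
        projection_axis=projection_axis,
    )
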