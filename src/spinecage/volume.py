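"""3-D scalar/label volumes with physical spacing.

World-coordinate convention (used everywhere in the package):
``world = index * spacing + origin`` with 0-based indices; array axis order is
(x, y, z), i.e. ``values[i, j, k]`` sits at
``origin + (i*sx, j*sy, k*sz)``.  SimpleITK stores arrays (z, y, x); the IO
functions transpose on the way in/out so users only ever see (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk


@dataclass
class ImageVolume:
    """A 3-D scalar grid (HU or labels) with mm spacing and origin."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (1-D arrays)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=values)


def to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write NIfTI (.nii/.nii.gz) or NRRD (.nrrd) depending on extension."""
    sitk.WriteImage(to_sitk(vol), str(path))


def read_volume(path: str | Path) -> ImageVolume:
    return from_sitk(sitk.ReadImage(str(path)))
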