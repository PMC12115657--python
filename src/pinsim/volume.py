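"""Attenuation volumes: 3D Hounsfield-unit grids with spacing and origin."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass
class AttenuationVolume:
    """A scalar CT-like grid.

    ``values[i, j, k]`` is the attenuation (HU) at physical position
    ``origin + (i, j, k) * spacing`` (voxel centers).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ParameterError("values must be a non-empty 3D grid")
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be positive on every axis")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("attenuation values must be finite")
        if self.origin.shape != (3,):
            raise ParameterError("origin must be a 3-vector")

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def save_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def load_nifti(cls, path) -> "AttenuationVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        return cls(
            values=np.asanyarray(img.dataobj).astype(float),
            spacing=spacing,
            origin=affine[:3, 3].astype(float),
        )
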