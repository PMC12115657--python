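"""Threshold segmentation and surface extraction.

Reproduces the CT workflow: a Hounsfield-unit window (default 226-3071 HU,
both bounds inclusive) produces a binary bone mask; marching cubes at the
0.5 level of the binary field turns each sufficiently large 26-connected
component into a watertight surface in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure as skmeasure

from .errors import AssignmentError, GeometryError, ParameterError
from .geometry import BoneSurface, points_in_mesh
from .volume import AttenuationVolume

DEFAULT_LO = 226.0
DEFAULT_HI = 3071.0


@dataclass
class BinaryMask:
    """Boolean grid aligned with its source volume, plus the HU window."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    window: Tuple[float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def count(self) -> int:
        return int(self.values.sum())


def threshold_segment(
    volume: AttenuationVolume, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> BinaryMask:
    """Binary bone mask: true exactly where ``lo <= HU <= hi`` (inclusive)."""
    if lo > hi:
        raise ParameterError(f"threshold window inverted: lo={lo} > hi={hi}")
    mask = (volume.values >= lo) & (volume.values <= hi)
    return BinaryMask(
        values=mask, spacing=volume.spacing, origin=volume.origin, window=(lo, hi)
    )


def mask_to_surface(
    mask: BinaryMask,
    min_component: int = 50,
    smooth_iterations: int = 0,
) -> List[BoneSurface]:
    """Extract one watertight surface per 26-connected mask component.

    Components smaller than ``min_component`` voxels are dropped.  The
    isosurface is taken at the 0.5 level of the binary field (no HU
    interpolation), scaled by the voxel spacing and offset by the volume
    origin.  ``smooth_iterations`` > 0 applies Taubin smoothing to each
    extracted surface: off by default (the raw 0.5-level surface is the
    faithful hard-threshold boundary), but recommended before normal-based
    thickness mapping, where staircase face normals mislead the rays.
    """
    if mask.count == 0:
        raise GeometryError("mask is empty; nothing to extract")
    labeled, n_comp = ndimage.label(mask.values, structure=np.ones((3, 3, 3)))
    surfaces = []
    slices = ndimage.find_objects(labeled)
    for comp_id, slc in enumerate(slices, start=1):
        comp = labeled[slc] == comp_id
        if comp.sum() < min_component:
            continue
        padded = np.pad(comp.astype(float), 1)
        verts, faces, _, _ = skmeasure.marching_cubes(
            padded, level=0.5, spacing=tuple(mask.spacing)
        )
        offset = (
            mask.origin
            + (np.array([s.start for s in slc]) - 1) * mask.spacing
        )
        mesh = trimesh.Trimesh(vertices=verts + offset, faces=faces, process=False)
        if not mesh.is_watertight:
            raise GeometryError("marching cubes produced an open component")
        if mesh.volume < 0:
            mesh.invert()
        if smooth_iterations > 0:
            trimesh.smoothing.filter_taubin(
                mesh, lamb=0.5, nu=-0.53, iterations=smooth_iterations
            )
        surf = BoneSurface(mesh=mesh, role="bone")
        surf.metadata["voxel_count"] = int(comp.sum())
        surfaces.append(surf)
    if not surfaces:
        raise GeometryError(
            f"all {n_comp} components fall below min_component={min_component}"
        )
    return surfaces


def split_components(
    surfaces: List[BoneSurface],
    seed_point=None,
    epiphysis_index: Optional[int] = None,
) -> Tuple[BoneSurface, BoneSurface]:
    """Assign one component to the epiphysis, merge the rest as remainder.

    The epiphysis is the component containing ``seed_point`` (a point known
    to lie inside the capitus), or the one at ``epiphysis_index`` when the
    caller already knows the labeling (synthetic data).
    """
    if len(surfaces) < 2:
        raise AssignmentError(
            "need at least two components (or separate masks) to split"
        )
    if epiphysis_index is None:
        if seed_point is None:
            raise AssignmentError("provide a seed_point or an epiphysis_index")
        seed_point = np.asarray(seed_point, dtype=float)
        hits = [
            i
            for i, s in enumerate(surfaces)
            if bool(points_in_mesh(s.mesh, seed_point[None])[0])
        ]
        if not hits:
            raise AssignmentError("seed point lies inside no component")
        epiphysis_index = hits[0]
    if not 0 <= epiphysis_index < len(surfaces):
        raise AssignmentError(f"epiphysis_index {epiphysis_index} out of range")
    epi = surfaces[epiphysis_index]
    rest = [s.mesh for i, s in enumerate(surfaces) if i != epiphysis_index]
    remainder_mesh = rest[0] if len(rest) == 1 else trimesh.util.concatenate(rest)
    epiphysis = BoneSurface(mesh=epi.mesh, role="epiphysis", metadata=dict(epi.metadata))
    remainder = BoneSurface(mesh=remainder_mesh, role="femur-remainder")
    return epiphysis, remainder
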