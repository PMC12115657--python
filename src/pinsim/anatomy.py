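"""Parametric synthetic proximal femora with known ground-truth geometry.

The generator emulates the segmented anatomy of a skeletally immature dog:
a capital epiphysis (spherical cap, optionally trimmed at its distal margin),
a planar physis separating it from the femur remainder (neck + shaft + third
trochanter), and named landmarks.  The canonical anatomical frame is a LEFT
femur with +x cranial, +y medial, +z proximal; right femora are mirror images
about the x-z plane.

Ground truth: with zero surface noise the maximal epiphyseal thickness,
measured along the inward surface normal from the subchondral dome to the
physeal plane, equals ``cap_height`` exactly (the pole chord), which is what
the thickness stage must recover.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh
from scipy import stats as sps
from skimage import measure as skmeasure

from .errors import GeometryError, ParameterError
from .geometry import (
    PHYSEAL,
    SUBCHONDRAL,
    BoneSurface,
    fill_planar_holes,
    mirror_transform,
    ray_mesh_intersections,
    unit,
)
from .volume import AttenuationVolume


def spherical_cap_volume(radius: float, height: float) -> float:
    """Closed-form volume of a spherical cap: pi * h^2 * (3r - h) / 3."""
    return math.pi * height**2 * (3.0 * radius - height) / 3.0


@dataclass
class FemurParams:
    """Parameters of one synthetic proximal femur (all lengths in mm).

    ``cap_radius``/``cap_height`` define the capital epiphysis as a spherical
    cap; ``cap_height`` is the ground-truth maximal epiphyseal thickness.
    ``physis_tilt`` tilts the physeal plane normal away from the proximal
    axis toward medial (the physis is more horizontal than the femoral
    neck); ``distal_trim_offset`` trims the cap with a second plane at the
    given distance distal to the cap axis, emulating the thin distal margin
    of a real epiphysis (``None`` disables the trim and yields the pure
    analytic cap).
    """

    cap_radius: float = 12.5
    cap_height: float = 11.8
    physis_tilt: float = 25.0
    physis_normal: Optional[Tuple[float, float, float]] = None
    neck_length: float = 8.0
    neck_radius: float = 5.0
    neck_shaft_angle: float = 135.0
    anteversion_angle: float = 15.0
    shaft_radius: float = 7.0
    shaft_length: float = 45.0
    trochanter_offset: float = 12.0
    trochanter_radius: float = 3.0
    distal_trim_offset: Optional[float] = None
    physis_gap: float = 0.05
    surface_noise_sd: float = 0.0
    side: str = "left"
    subdivisions: int = 4
    remainder_spacing: float = 0.7

    def validate(self) -> None:
        positive = [
            "cap_radius",
            "cap_height",
            "neck_length",
            "neck_radius",
            "shaft_radius",
            "shaft_length",
            "trochanter_offset",
            "trochanter_radius",
            "remainder_spacing",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 < self.cap_height < 2 * self.cap_radius:
            raise ParameterError("cap_height must lie in (0, 2*cap_radius)")
        if not 90.0 < self.neck_shaft_angle < 180.0:
            raise ParameterError("neck_shaft_angle must lie in (90, 180) degrees")
        if not 0.0 <= self.anteversion_angle <= 45.0:
            raise ParameterError("anteversion_angle must lie in [0, 45] degrees")
        if self.surface_noise_sd < 0:
            raise ParameterError("surface_noise_sd must be >= 0")
        if not 0.01 <= self.physis_gap <= 0.1:
            raise ParameterError("physis_gap must lie in [0.01, 0.1] mm")
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        if self.distal_trim_offset is not None and self.distal_trim_offset <= 0:
            raise ParameterError("distal_trim_offset must be > 0 or None")

    def resolved_physis_normal(self) -> np.ndarray:
        """Physeal plane normal in the canonical (left) frame."""
        if self.physis_normal is not None:
            return unit(self.physis_normal)
        t = math.radians(self.physis_tilt)
        a = math.radians(self.anteversion_angle)
        return np.array(
            [math.sin(t) * math.sin(a), math.sin(t) * math.cos(a), math.cos(t)]
        )

    def neck_direction(self) -> np.ndarray:
        """Unit vector along the femoral neck (shaft junction -> head center)."""
        t = math.radians(180.0 - self.neck_shaft_angle)
        a = math.radians(self.anteversion_angle)
        return np.array(
            [math.sin(t) * math.sin(a), math.sin(t) * math.cos(a), math.cos(t)]
        )


@dataclass
class CohortParams:
    """Cohort-level generation parameters.

    Defaults emulate the study cohort: 16 specimens with maximal epiphyseal
    thickness drawn from a truncated normal with mean 11.8 mm and SD 2.0 mm.
    ``jitter`` gives half-widths of uniform perturbations applied to the base
    femur parameters so specimens differ in more than cap height.
    """

    n_specimens: int = 16
    cap_height_mean: float = 11.8
    cap_height_sd: float = 2.0
    seed: int = 0
    base: FemurParams = field(
        default_factory=lambda: FemurParams(distal_trim_offset=0.75)
    )
    jitter: Dict[str, float] = field(
        default_factory=lambda: {
            "cap_radius": 0.8,
            "neck_length": 1.0,
            "neck_radius": 0.5,
            "neck_shaft_angle": 5.0,
            "anteversion_angle": 5.0,
            "shaft_radius": 0.5,
            "trochanter_offset": 2.0,
        }
    )
    truncation_lo: float = 2.0

    def validate(self) -> None:
        if self.n_specimens < 1:
            raise ParameterError("n_specimens must be >= 1")
        if self.cap_height_sd < 0:
            raise ParameterError("cap_height_sd must be >= 0")
        for key in self.jitter:
            if not hasattr(FemurParams, "__dataclass_fields__") or key not in FemurParams.__dataclass_fields__:
                raise ParameterError(f"unknown jitter parameter '{key}'")


@dataclass
class LandmarkSet:
    """Named anatomical points plus the canonical orthonormal axes."""

    third_trochanter: np.ndarray
    capitus_pole: np.ndarray
    physis_centroid: np.ndarray
    cranial: np.ndarray
    medial: np.ndarray
    proximal: np.ndarray

    def __post_init__(self):
        for name in ("third_trochanter", "capitus_pole", "physis_centroid"):
            value = np.asarray(getattr(self, name), dtype=float)
            if value.shape != (3,) or not np.all(np.isfinite(value)):
                raise ParameterError(f"landmark '{name}' must be a finite 3-vector")
            setattr(self, name, value)
        axes = np.stack(
            [np.asarray(getattr(self, n), dtype=float) for n in ("cranial", "medial", "proximal")]
        )
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ParameterError("canonical axes must be mutually orthonormal")
        self.cranial, self.medial, self.proximal = axes

    def physis_normal(self, params: FemurParams) -> np.ndarray:
        """Physeal normal expressed in this landmark frame.

        The normal's canonical (left-femur) components ride on the carried
        anatomical axes, so mirroring and rigid motion of the landmarks
        automatically carry the physis orientation along.
        """
        n = params.resolved_physis_normal()
        return n[0] * self.cranial + n[1] * self.medial + n[2] * self.proximal

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        R = np.asarray(matrix)[:3, :3]
        t = np.asarray(matrix)[:3, 3]
        return LandmarkSet(
            third_trochanter=R @ self.third_trochanter + t,
            capitus_pole=R @ self.capitus_pole + t,
            physis_centroid=R @ self.physis_centroid + t,
            cranial=R @ self.cranial,
            medial=R @ self.medial,
            proximal=R @ self.proximal,
        )

    def to_json(self, path) -> None:
        data = {k: np.asarray(v).tolist() for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**{k: np.asarray(v) for k, v in data.items()})


@dataclass
class Specimen:
    """One generated specimen with its surfaces and ground truth."""

    specimen_id: str
    seed: int
    params: FemurParams
    epiphysis: BoneSurface
    remainder: BoneSurface
    landmarks: LandmarkSet
    ground_truth: dict


def _distal_tangent(physis_normal: np.ndarray) -> np.ndarray:
    """In-physis-plane unit vector pointing distally (toward the shaft)."""
    down = np.array([0.0, 0.0, -1.0])
    g = down - np.dot(down, physis_normal) * physis_normal
    return unit(g)


def _build_epiphysis(params: FemurParams) -> Tuple[trimesh.Trimesh, np.ndarray]:
    """Spherical-cap epiphysis in the canonical left frame, with face labels."""
    r, h = params.cap_radius, params.cap_height
    n_phys = params.resolved_physis_normal()
    sphere = trimesh.creation.icosphere(subdivisions=params.subdivisions, radius=r)
    base_origin = (r - h) * n_phys
    dome = trimesh.intersections.slice_mesh_plane(
        sphere, plane_normal=n_phys, plane_origin=base_origin, cap=False
    )
    capped, _ = fill_planar_holes(dome)
    if params.distal_trim_offset is not None:
        g = _distal_tangent(n_phys)
        trimmed = trimesh.intersections.slice_mesh_plane(
            capped,
            plane_normal=-g,
            plane_origin=params.distal_trim_offset * g,
            cap=False,
        )
        if len(trimmed.faces) == 0:
            raise GeometryError("distal_trim_offset removed the entire epiphysis")
        capped, _ = fill_planar_holes(trimmed)
    mesh = trimesh.Trimesh(
        vertices=capped.vertices.copy(), faces=capped.faces.copy(), process=False
    )
    if not mesh.is_watertight:
        raise GeometryError("epiphysis construction produced an open mesh")
    if mesh.volume < 0:
        mesh.invert()
    # Label faces: all three vertices on the physeal plane -> physeal.
    plane_dist = mesh.vertices @ n_phys - (r - h)
    on_plane = np.abs(plane_dist) < 1e-6
    labels = np.where(on_plane[mesh.faces].all(axis=1), PHYSEAL, SUBCHONDRAL)
    if not (labels == PHYSEAL).any():
        raise GeometryError("no physeal faces produced")
    return mesh, labels


def _capsule_sdf(points, a, b, radius):
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1) - radius


def _build_remainder(params: FemurParams) -> trimesh.Trimesh:
    """Neck + shaft + third-trochanter solid via a signed distance field.

    Marching cubes at level 0 of the analytic SDF gives a watertight,
    self-intersection-free surface with sub-voxel accuracy; the physeal gap
    plane enters the SDF as an exact linear field, so the flat cut facing
    the physis is reproduced to machine precision.
    """
    r, h = params.cap_radius, params.cap_height
    n_phys = params.resolved_physis_normal()
    n_neck = params.neck_direction()
    C = np.zeros(3)
    J = C - params.neck_length * n_neck
    shaft_end = J + np.array([0.0, 0.0, -params.shaft_length])
    troch_center = J + np.array(
        [0.0, -params.shaft_radius, -params.trochanter_offset]
    )
    gap_level = (r - h) - params.physis_gap

    pts = np.array([C, J, shaft_end, troch_center])
    radii = np.array(
        [
            params.neck_radius,
            max(params.neck_radius, params.shaft_radius),
            params.shaft_radius,
            params.trochanter_radius,
        ]
    )
    lo = (pts - radii[:, None]).min(axis=0) - 2 * params.remainder_spacing
    hi = (pts + radii[:, None]).max(axis=0) + 2 * params.remainder_spacing
    spacing = params.remainder_spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    xs = lo[0] + np.arange(shape[0]) * spacing
    ys = lo[1] + np.arange(shape[1]) * spacing
    zs = lo[2] + np.arange(shape[2]) * spacing
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    sdf = np.minimum(
        _capsule_sdf(grid, J, C, params.neck_radius),
        _capsule_sdf(grid, J, shaft_end, params.shaft_radius),
    )
    sdf = np.minimum(
        sdf, np.linalg.norm(grid - troch_center, axis=1) - params.trochanter_radius
    )
    # Clip everything proximal to the physeal gap plane.
    sdf = np.maximum(sdf, grid @ n_phys - gap_level)
    sdf = sdf.reshape(shape)

    verts, faces, _, _ = skmeasure.marching_cubes(
        sdf, level=0.0, spacing=(spacing, spacing, spacing)
    )
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=False)
    if not mesh.is_watertight:
        raise GeometryError("remainder construction produced an open mesh")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def generate_femur(
    params: FemurParams, seed: int = 0
) -> Tuple[BoneSurface, BoneSurface, LandmarkSet, dict]:
    """Generate one synthetic proximal femur.

    Returns the epiphysis surface (face-labeled subchondral/physeal), the
    femur remainder, the landmark set, and a ground-truth record.  With
    ``surface_noise_sd = 0`` the analytic maximal thickness equals
    ``cap_height``; right-sided femora are exact mirror images of the
    left-sided model generated with the same seed.
    """
    params.validate()
    r, h = params.cap_radius, params.cap_height
    n_phys = params.resolved_physis_normal()
    n_neck = params.neck_direction()

    epi_mesh, labels = _build_epiphysis(params)
    rem_mesh = _build_remainder(params)

    rng = np.random.default_rng(seed)
    if params.surface_noise_sd > 0:
        for mesh in (epi_mesh, rem_mesh):
            disp = rng.normal(0.0, params.surface_noise_sd, size=len(mesh.vertices))
            mesh.vertices = mesh.vertices + disp[:, None] * mesh.vertex_normals

    C = np.zeros(3)
    J = C - params.neck_length * n_neck
    landmarks = LandmarkSet(
        third_trochanter=J
        + np.array(
            [
                0.0,
                -(params.shaft_radius + params.trochanter_radius),
                -params.trochanter_offset,
            ]
        ),
        capitus_pole=C + r * n_phys,
        physis_centroid=C + (r - h) * n_phys,
        cranial=np.array([1.0, 0.0, 0.0]),
        medial=np.array([0.0, 1.0, 0.0]),
        proximal=np.array([0.0, 0.0, 1.0]),
    )

    epiphysis = BoneSurface(mesh=epi_mesh, role="epiphysis", face_labels=labels)
    remainder = BoneSurface(mesh=rem_mesh, role="femur-remainder")
    if params.side == "right":
        M = mirror_transform()
        epiphysis = epiphysis.transformed(M)
        remainder = remainder.transformed(M)
        landmarks = landmarks.transformed(M)

    ground_truth = {
        "max_thickness": h,
        "cap_volume_analytic": (
            spherical_cap_volume(r, h) if params.distal_trim_offset is None else None
        ),
        "capitus_pole": landmarks.capitus_pole.tolist(),
        "physis_normal": landmarks.physis_normal(params).tolist(),
        "side": params.side,
    }
    return epiphysis, remainder, landmarks, ground_truth


def sample_cohort_params(cohort: CohortParams) -> List[Tuple[str, int, FemurParams]]:
    """Draw per-specimen parameters (no meshes built); reproducible from seed.

    Cap heights come from a normal distribution truncated to
    ``(truncation_lo, 2*cap_radius - 0.5)``; the cap radius is floored at
    ``cap_height + 0.5`` so the epiphysis stays at most hemispherical and the
    pole chord remains the ground-truth maximal thickness.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    out = []
    for i in range(cohort.n_specimens):
        jittered = {
            key: getattr(cohort.base, key) + rng.uniform(-half, half)
            for key, half in sorted(cohort.jitter.items())
        }
        cap_radius = jittered.get("cap_radius", cohort.base.cap_radius)
        lo, hi = cohort.truncation_lo, 2.0 * cap_radius - 0.5
        if lo >= hi:
            raise ParameterError(
                f"cap-height truncation bounds inverted: ({lo}, {hi})"
            )
        if cohort.cap_height_sd == 0:
            cap_height = float(np.clip(cohort.cap_height_mean, lo, hi))
            rng.uniform()  # keep the draw sequence aligned with sd > 0
        else:
            a = (lo - cohort.cap_height_mean) / cohort.cap_height_sd
            b = (hi - cohort.cap_height_mean) / cohort.cap_height_sd
            cap_height = float(
                sps.truncnorm.ppf(
                    rng.uniform(),
                    a,
                    b,
                    loc=cohort.cap_height_mean,
                    scale=cohort.cap_height_sd,
                )
            )
        jittered["cap_radius"] = max(cap_radius, cap_height + 0.5)
        params = dataclasses.replace(cohort.base, cap_height=cap_height, **jittered)
        seed = int(rng.integers(0, 2**31 - 1))
        out.append((f"S{i + 1:02d}", seed, params))
    return out


def generate_cohort(cohort: CohortParams) -> List[Specimen]:
    """Generate a full synthetic cohort (meshes, landmarks, ground truth)."""
    specimens = []
    for specimen_id, seed, params in sample_cohort_params(cohort):
        epi, rem, lm, gt = generate_femur(params, seed=seed)
        specimens.append(
            Specimen(
                specimen_id=specimen_id,
                seed=seed,
                params=params,
                epiphysis=epi,
                remainder=rem,
                landmarks=lm,
                ground_truth=gt,
            )
        )
    return specimens


def cohort_manifest(specimens: List[Specimen]):
    """Per-specimen parameter manifest as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for sp in specimens:
        row = {"specimen_id": sp.specimen_id, "seed": sp.seed}
        row.update(
            {
                k: (v if not isinstance(v, tuple) else json.dumps(v))
                for k, v in dataclasses.asdict(sp.params).items()
            }
        )
        row["ground_truth_max_thickness_mm"] = sp.ground_truth["max_thickness"]
        rows.append(row)
    return pd.DataFrame(rows)


def voxelize(
    surfaces,
    spacing,
    hu_bone: float = 1000.0,
    hu_background: float = -1000.0,
    pad_voxels: int = 2,
) -> AttenuationVolume:
    """Rasterize watertight surfaces into an attenuation volume.

    A voxel receives ``hu_bone`` exactly when its center lies inside any of
    the surfaces (even-odd rule along grid columns), else ``hu_background``.
    The grid pads the combined bounding box by ``pad_voxels`` voxels.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ParameterError("spacing must be positive on every axis")
    meshes = []
    for surf in surfaces:
        mesh = surf.mesh if isinstance(surf, BoneSurface) else surf
        if not mesh.is_watertight:
            raise GeometryError("voxelize requires watertight surfaces")
        meshes.append(mesh)

    if meshes:
        lo = np.min([m.bounds[0] for m in meshes], axis=0)
        hi = np.max([m.bounds[1] for m in meshes], axis=0)
    else:
        lo = np.zeros(3)
        hi = np.zeros(3)
    # Half-voxel offset: voxel centers straddle the geometry boundary instead
    # of landing exactly on axis-aligned faces (keeps the even-odd rule crisp).
    origin = lo - (pad_voxels - 0.5) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + 1 + pad_voxels
    values = np.full(shape, float(hu_background))

    if meshes:
        xs = origin[0] + np.arange(shape[0]) * spacing[0]
        ys = origin[1] + np.arange(shape[1]) * spacing[1]
        zs = origin[2] + np.arange(shape[2]) * spacing[2]
        # Column rays along +z, origins nudged off lattice symmetry planes.
        eps = 1e-4 * spacing[:2]
        gx, gy = np.meshgrid(xs + eps[0], ys + eps[1], indexing="ij")
        origins = np.stack(
            [gx.ravel(), gy.ravel(), np.full(gx.size, zs[0] - spacing[2])], axis=1
        )
        dirs = np.tile([0.0, 0.0, 1.0], (len(origins), 1))
        inside = np.zeros(shape, dtype=bool)
        for mesh in meshes:
            ray_idx, t, _ = ray_mesh_intersections(mesh, origins, dirs)
            z_hits = origins[0, 2] + t
            split = np.searchsorted(ray_idx, np.arange(len(origins)))
            split = np.append(split, len(ray_idx))
            for col in range(len(origins)):
                crossings = z_hits[split[col] : split[col + 1]]
                n_pairs = len(crossings) // 2
                for k in range(n_pairs):
                    z0, z1 = crossings[2 * k], crossings[2 * k + 1]
                    i0 = int(np.ceil((z0 - zs[0]) / spacing[2] - 1e-12))
                    i1 = int(np.floor((z1 - zs[0]) / spacing[2] + 1e-12))
                    if i1 >= i0:
                        ci, cj = divmod(col, shape[1])
                        inside[ci, cj, max(i0, 0) : i1 + 1] = True
        values[inside] = float(hu_bone)

    return AttenuationVolume(values=values, spacing=spacing, origin=origin)
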