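"""Thickness mapping: face classification, ray casting, maximum location."""

import dataclasses
import math

import numpy as np
import pytest
import trimesh

from pinsim.anatomy import FemurParams, generate_femur
from pinsim.errors import GeometryError
from pinsim.geometry import PHYSEAL, SUBCHONDRAL, BoneSurface
from pinsim.thickness import (
    ThicknessField,
    classify_faces,
    max_thickness,
    thickness_field,
)

from conftest import make_slab


def cap_thickness_oracle(cap_radius, cap_height, n=20000, seed=0):
    """Dense analytic sweep over a spherical cap: thickness per direction.

    For a cap of radius r and height h <= r, the inward-normal chord from a
    surface direction with polar cosine c exits through the physeal plane at
    t = r - (r - h)/c when that crossing lies inside the base disc, and
    through the dome otherwise (such grazing chords are discarded).
    """
    r, h = cap_radius, cap_height
    rng = np.random.default_rng(seed)
    c = rng.uniform((r - h) / r, 1.0, size=n)  # directions on the cap
    t = r - (r - h) / c
    base_r = np.sqrt(h * (2 * r - h))
    off_axis = (r - h) * np.sqrt(1.0 / c**2 - 1.0)
    return t[(t > 0) & (off_axis <= base_r)]


def test_classify_flat_base_is_physeal(pure_cap_specimen):
    params, epi, _, lm, _ = pure_cap_specimen
    labels = classify_faces(epi, lm.physis_normal(params))
    n = lm.physis_normal(params)
    base_faces = labels == PHYSEAL
    # every physeal face has its outward normal along -physis_normal
    dots = epi.mesh.face_normals[base_faces] @ (-n)
    assert (dots > 0.999).all()
    # and the physeal set is exactly the flat base: area matches pi*a^2
    a2 = params.cap_height * (2 * params.cap_radius - params.cap_height)
    assert epi.mesh.area_faces[base_faces].sum() == pytest.approx(
        math.pi * a2, rel=0.01
    )


def test_classify_noisy_cap_base_area():
    params = FemurParams(cap_radius=10.0, cap_height=8.0, surface_noise_sd=0.05)
    epi, _, lm, _ = generate_femur(params, seed=7)
    labels = classify_faces(epi, lm.physis_normal(params))
    area = epi.mesh.area_faces[labels == PHYSEAL].sum()
    assert area == pytest.approx(math.pi * 96.0, rel=0.05)


def test_classify_zero_cone_on_noisy_mesh_errors():
    params = FemurParams(cap_radius=10.0, cap_height=8.0, surface_noise_sd=0.05)
    epi, _, lm, _ = generate_femur(params, seed=7)
    with pytest.raises(GeometryError):
        classify_faces(epi, lm.physis_normal(params), cone_half_angle_deg=0.0)


def test_slab_thickness_uniform():
    slab = make_slab(thickness=12.0)
    fld = thickness_field(slab, n_samples=200)
    assert np.abs(fld.values - 12.0).max() < 0.01
    assert fld.max_thickness == pytest.approx(12.0, abs=0.01)


def test_sphere_all_subchondral_measures_diameter():
    """With labels overridden and grazing discard off, rays span the sphere."""
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=6.0)
    surf = BoneSurface(
        mesh=sphere,
        role="epiphysis",
        face_labels=np.full(len(sphere.faces), SUBCHONDRAL),
    )
    fld = thickness_field(surf, n_samples=100, discard_grazing=False)
    assert np.abs(fld.values - 12.0).max() < 0.05


def test_cap_max_thickness_matches_height_and_pole(pure_cap_specimen):
    params, epi, _, lm, _ = pure_cap_specimen
    labels = classify_faces(epi, lm.physis_normal(params))
    fld = thickness_field(epi, labels, n_samples=2000)
    assert fld.max_thickness == pytest.approx(8.0, abs=0.05)
    assert np.linalg.norm(fld.max_point - lm.capitus_pole) < 0.5
    # the dense analytic sweep agrees on the supremum
    oracle = cap_thickness_oracle(10.0, 8.0)
    assert fld.max_thickness == pytest.approx(oracle.max(), abs=0.05)
    # and every accepted sample respects the analytic bound
    assert fld.values.max() <= 8.0 + 0.05


@pytest.mark.parametrize("seed", range(4))
def test_cap_oracle_random_geometries(seed):
    """Random (r, h): measured maximum equals the cap height within 0.05 mm."""
    rng = np.random.default_rng(seed)
    r = rng.uniform(9.0, 14.0)
    h = rng.uniform(0.55 * r, 0.95 * r)
    params = FemurParams(cap_radius=r, cap_height=h)
    epi, _, lm, _ = generate_femur(params, seed=seed)
    labels = classify_faces(epi, lm.physis_normal(params))
    fld = thickness_field(epi, labels, n_samples=1200)
    assert abs(fld.max_thickness - h) < 0.05


def test_max_thickness_singleton_and_tie_rule():
    pts = np.array([[0.0, 0, 0], [10.0, 0, 0], [10.2, 0, 0], [5.0, 0, 0]])
    nrm = np.tile([0.0, 0, -1.0], (4, 1))
    fld = ThicknessField(
        points=pts[:1], normals=nrm[:1], values=np.array([5.0]),
        face_areas=np.array([1.0]),
    )
    p, v, ax = max_thickness(fld)
    np.testing.assert_allclose(p, [0, 0, 0])
    assert v == 5.0
    # two exact ties: pick the one nearer the area-weighted centroid of the
    # top-percentile samples (the larger face at x=10 pulls it rightward)
    fld = ThicknessField(
        points=pts, normals=nrm,
        values=np.array([7.0, 7.0, 6.9, 1.0]),
        face_areas=np.array([1.0, 3.0, 1.0, 1.0]),
    )
    p, v, _ = max_thickness(fld)
    assert v == 7.0
    assert p[0] == 10.0


def test_rigid_invariance(pure_cap_specimen):
    """Rotating and translating the epiphysis leaves the maximum unchanged."""
    params, epi, _, lm, _ = pure_cap_specimen
    labels = classify_faces(epi, lm.physis_normal(params))
    base = thickness_field(epi, labels, n_samples=600).max_thickness
    angle = 0.7
    T = trimesh.transformations.rotation_matrix(angle, [0.3, 0.5, 0.8])
    T[:3, 3] = [4.0, -7.0, 2.5]
    moved = epi.transformed(T)
    moved_lm = lm.transformed(T)
    labels2 = classify_faces(moved, moved_lm.physis_normal(params))
    got = thickness_field(moved, labels2, n_samples=600).max_thickness
    assert abs(got - base) < 0.01


def test_refinement_stability(default_specimen):
    sp = default_specimen
    labels = classify_faces(sp.epiphysis, sp.landmarks.physis_normal(sp.params))
    m1 = thickness_field(sp.epiphysis, labels, n_samples=400).max_thickness
    m2 = thickness_field(sp.epiphysis, labels, n_samples=800).max_thickness
    assert abs(m2 - m1) / m2 < 0.02


def test_too_few_valid_rays_errors():
    slab = make_slab(thickness=12.0)
    with pytest.raises(GeometryError):
        thickness_field(slab, n_samples=10, min_valid=10000)
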