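"""Shared fixtures: analytic test solids and generated specimens."""

import numpy as np
import pytest
import trimesh

from pinsim.anatomy import CohortParams, FemurParams, generate_cohort, generate_femur
from pinsim.geometry import PHYSEAL, SUBCHONDRAL, BoneSurface


def make_slab(thickness=12.0, width=40.0, edge=2.0):
    """A flat slab (bottom at z=0) with the top face labeled subchondral."""
    box = trimesh.creation.box(extents=[width, width, thickness])
    box.apply_translation([0.0, 0.0, thickness / 2.0])
    box = box.subdivide_to_size(edge)
    box.merge_vertices()
    labels = np.where(box.face_normals[:, 2] > 0.9, SUBCHONDRAL, PHYSEAL)
    return BoneSurface(mesh=box, role="epiphysis", face_labels=labels)


def slab_inside(points, thickness=12.0, width=40.0):
    """Analytic containment for the slab above."""
    points = np.atleast_2d(points)
    return (
        (np.abs(points[:, 0]) <= width / 2)
        & (np.abs(points[:, 1]) <= width / 2)
        & (points[:, 2] >= 0)
        & (points[:, 2] <= thickness)
    )


def cap_inside(points, cap_radius, cap_height, physis_normal, trim_offset=None,
               trim_direction=None):
    """Analytic containment for a spherical cap centered at the origin."""
    points = np.atleast_2d(points)
    inside = (np.linalg.norm(points, axis=1) <= cap_radius) & (
        points @ physis_normal >= cap_radius - cap_height
    )
    if trim_offset is not None:
        inside &= points @ trim_direction <= trim_offset
    return inside


def brute_segment_length(inside_fn, p0, p1, step=2e-3):
    """Independent purchase oracle: point-in-solid sampling along a segment."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    n = max(1, int(np.ceil(length / step)))
    ts = (np.arange(n) + 0.5) * (length / n)
    pts = p0 + np.outer(ts, (p1 - p0) / length)
    return inside_fn(pts).sum() * (length / n)


@pytest.fixture(scope="session")
def pure_cap_specimen():
    """Analytic-cap femur (r=10, h=8, no trim, no noise) with ground truth."""
    params = FemurParams(cap_radius=10.0, cap_height=8.0)
    epi, rem, lm, gt = generate_femur(params, seed=42)
    return params, epi, rem, lm, gt

@pytest.fixture(scope="session")
def default_cohort_small():
    """Four specimens from the default cohort generator (fixed seed)."""
    return generate_cohort(CohortParams(n_specimens=4, seed=5))


@pytest.fixture(scope="session")
def default_specimen(default_cohort_small):
    return default_cohort_small[0]
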