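"""Wire planning: trajectories, pattern offsets, placement, safety checks."""

import logging

import numpy as np
import pytest
import trimesh

from pinsim.anatomy import CohortParams, LandmarkSet, generate_cohort
from pinsim.errors import GeometryError, PlacementError
from pinsim.geometry import BoneSurface, PHYSEAL, mirror_transform
from pinsim.planner import (
    LINEAR,
    TRIANGULAR,
    Wire,
    central_trajectory,
    detect_penetration,
    pattern_offsets,
    place_pattern,
)
from pinsim.metrics import wire_purchase
from pinsim.thickness import classify_faces, thickness_field

from conftest import make_slab


CANONICAL = LandmarkSet(
    third_trochanter=[0.0, 0, 0],
    capitus_pole=[1.0, 1, 1],
    physis_centroid=[0.5, 0.5, 0.5],
    cranial=[1.0, 0, 0],
    medial=[0.0, 1, 0],
    proximal=[0.0, 0, 1],
)


def _analyze(specimen):
    labels = classify_faces(
        specimen.epiphysis, specimen.landmarks.physis_normal(specimen.params)
    )
    specimen.epiphysis.face_labels = labels
    fld = thickness_field(specimen.epiphysis, labels, n_samples=600)
    traj = central_trajectory(specimen.landmarks, fld.max_point)
    return fld, traj


def test_trajectory_is_normalized_difference():
    start, d = central_trajectory(CANONICAL, [1.0, 1.0, 1.0])
    np.testing.assert_allclose(start, [0, 0, 0])
    np.testing.assert_allclose(d, np.ones(3) / np.sqrt(3))


def test_trajectory_warns_but_returns_on_wrong_direction(caplog):
    with caplog.at_level(logging.WARNING, logger="pinsim.planner"):
        start, d = central_trajectory(CANONICAL, [1.0, -1.0, 1.0])
    assert "not craniomedially" in caplog.text
    np.testing.assert_allclose(np.linalg.norm(d), 1.0)


def test_trajectory_rejects_coincident_points():
    with pytest.raises(GeometryError):
        central_trajectory(CANONICAL, [0.0, 0.0, 0.0])


def test_default_specimen_trajectory_direction(default_specimen):
    """The generator places the trochanter so the approach is craniomedial."""
    sp = default_specimen
    fld, (start, d) = _analyze(sp)
    lm = sp.landmarks
    assert d @ lm.cranial > 0
    assert d @ lm.medial > 0
    assert d @ lm.proximal > 0


def test_pattern_offsets_spacing_zero_degenerate():
    d = np.array([0.0, 1.0, 0.0])
    for arrangement in (LINEAR, TRIANGULAR):
        offs = pattern_offsets(arrangement, 0.0, d, CANONICAL)
        np.testing.assert_allclose(offs, 0.0)


def test_pattern_offsets_pairwise_distances():
    d = np.array([0.2, 0.9, 0.4])
    d /= np.linalg.norm(d)
    lin = pattern_offsets(LINEAR, 2.0, d, CANONICAL)
    assert np.linalg.norm(lin[0] - lin[1]) == pytest.approx(2.0, abs=1e-9)
    assert np.linalg.norm(lin[1] - lin[2]) == pytest.approx(2.0, abs=1e-9)
    assert np.linalg.norm(lin[0] - lin[2]) == pytest.approx(4.0, abs=1e-9)
    tri = pattern_offsets(TRIANGULAR, 2.0, d, CANONICAL)
    for a, b in ((0, 1), (1, 2), (0, 2)):
        assert np.linalg.norm(tri[a] - tri[b]) == pytest.approx(2.0, abs=1e-9)
    np.testing.assert_allclose(tri.mean(axis=0), 0.0, atol=1e-12)
    # all offsets perpendicular to the trajectory
    np.testing.assert_allclose(tri @ d, 0.0, atol=1e-12)
    # wire 1 proximal; wires 2 and 3 split cranially/caudally
    assert tri[0] @ CANONICAL.proximal > 0
    assert tri[1] @ CANONICAL.cranial > 0
    assert tri[2] @ CANONICAL.cranial < 0


def test_pattern_offsets_degenerate_direction_errors():
    with pytest.raises(GeometryError):
        pattern_offsets(LINEAR, 2.0, [0.0, 0.0, 1.0], CANONICAL)


def test_slab_placement_tip_depth():
    """Perpendicular wires into a slab stop exactly setback below the top."""
    slab = make_slab(thickness=12.0)
    remainder = make_slab(thickness=4.0)
    remainder.mesh.apply_translation([0, 0, -8.0])
    remainder.role = "femur-remainder"
    trajectory = (np.array([0.5, -0.3, -8.0]), np.array([0.0, 0.0, 1.0]))
    # the slab is drilled along +z, so use a frame whose proximal axis is
    # not parallel to the trajectory (offsets live in the x-y plane)
    frame = LandmarkSet(
        third_trochanter=[0.0, 0, 0],
        capitus_pole=[1.0, 1, 1],
        physis_centroid=[0.5, 0.5, 0.5],
        cranial=[0.0, 1, 0],
        medial=[0.0, 0, 1],
        proximal=[1.0, 0, 0],
    )
    offsets = pattern_offsets(LINEAR, 2.0, trajectory[1], frame)
    pattern = place_pattern(slab, remainder, trajectory, offsets, tip_setback=2.0)
    for wire in pattern.wires:
        assert wire.tip[2] == pytest.approx(10.0, abs=1e-9)
    pattern.check_invariants(slab)


def test_default_specimen_all_wires_inside_capitus():
    """On the default anatomy all six tips seat inside the capitus."""
    import dataclasses
    from pinsim.anatomy import Specimen, generate_femur
    from pinsim.geometry import points_in_mesh

    params = CohortParams().base  # default anatomy incl. distal margin trim
    epi, rem, lm, gt = generate_femur(params, seed=0)
    sp = Specimen("default", 0, params, epi, rem, lm, gt)
    fld, traj = _analyze(sp)
    for arrangement in (LINEAR, TRIANGULAR):
        offs = pattern_offsets(arrangement, 2.0, traj[1], sp.landmarks)
        pattern = place_pattern(
            sp.epiphysis, sp.remainder, traj, offs, arrangement=arrangement
        )
        tips = np.stack([w.tip for w in pattern.wires])
        assert points_in_mesh(sp.epiphysis.mesh, tips).all()


def test_synthetic_cohort_wires_safe(default_cohort_small):
    """Both arrangements on random specimens: invariants hold, no penetration.

    (A linear distal wire may legitimately end with zero purchase when the
    thin distal margin leaves less bone than the tip setback; safety means
    setback and no articular penetration, which hold for every wire.)
    """
    for sp in default_cohort_small:
        fld, traj = _analyze(sp)
        for arrangement in (LINEAR, TRIANGULAR):
            offs = pattern_offsets(arrangement, 2.0, traj[1], sp.landmarks)
            pattern = place_pattern(
                sp.epiphysis, sp.remainder, traj, offs, arrangement=arrangement
            )
            pattern.check_invariants(sp.epiphysis)
            for wire in pattern.wires:
                flag, overshoot = detect_penetration(wire, sp.epiphysis)
                assert not flag and overshoot == 0.0


def test_missed_trajectory_raises_with_indices(default_specimen):
    sp = default_specimen
    fld, (start, d) = _analyze(sp)
    off_target = (start + np.array([0.0, 0.0, -60.0]), d)
    offsets = pattern_offsets(LINEAR, 2.0, d, sp.landmarks)
    with pytest.raises(PlacementError) as err:
        place_pattern(sp.epiphysis, sp.remainder, off_target, offsets)
    assert set(err.value.missed) <= {1, 2, 3}
    assert len(err.value.missed) >= 1


def test_detect_penetration_translate_oracle(default_specimen):
    sp = default_specimen
    fld, traj = _analyze(sp)
    offsets = pattern_offsets(LINEAR, 2.0, traj[1], sp.landmarks)
    pattern = place_pattern(sp.epiphysis, sp.remainder, traj, offsets)
    wire = pattern.wires[1]
    flag, overshoot = detect_penetration(wire, sp.epiphysis)
    assert not flag and overshoot == 0.0
    pushed = Wire(
        index=wire.index,
        diameter=wire.diameter,
        tip=wire.tip + 3.0 * wire.axis,
        entry=wire.entry,
        axis=wire.axis,
        pattern=wire.pattern,
    )
    flag, overshoot = detect_penetration(pushed, sp.epiphysis)
    assert flag and overshoot == pytest.approx(1.0, abs=1e-6)
    boundary = Wire(
        index=wire.index,
        diameter=wire.diameter,
        tip=wire.tip + 2.0 * wire.axis,  # exactly on the subchondral surface
        entry=wire.entry,
        axis=wire.axis,
        pattern=wire.pattern,
    )
    flag, overshoot = detect_penetration(boundary, sp.epiphysis)
    assert not flag and overshoot == pytest.approx(0.0, abs=1e-6)


def test_spacing_zero_patterns_converge(default_specimen):
    sp = default_specimen
    fld, traj = _analyze(sp)
    purchases = {}
    for arrangement in (LINEAR, TRIANGULAR):
        offs = pattern_offsets(arrangement, 0.0, traj[1], sp.landmarks)
        pattern = place_pattern(
            sp.epiphysis, sp.remainder, traj, offs, arrangement=arrangement
        )
        purchases[arrangement] = [
            wire_purchase(w, sp.epiphysis) for w in pattern.wires
        ]
    np.testing.assert_allclose(
        purchases[LINEAR], purchases[TRIANGULAR], atol=1e-6
    )


def test_mirror_equivariance_of_purchases():
    """Right-sided anatomy yields the mirrored pattern and equal purchases."""
    import dataclasses

    cohort = CohortParams(n_specimens=1, seed=77)
    left = generate_cohort(cohort)[0]
    cohort_r = CohortParams(n_specimens=1, seed=77)
    cohort_r.base = dataclasses.replace(cohort_r.base, side="right")
    right = generate_cohort(cohort_r)[0]
    out = {}
    for sp, tag in ((left, "left"), (right, "right")):
        fld, traj = _analyze(sp)
        vals = []
        for arrangement in (LINEAR, TRIANGULAR):
            offs = pattern_offsets(arrangement, 2.0, traj[1], sp.landmarks)
            pattern = place_pattern(
                sp.epiphysis, sp.remainder, traj, offs, arrangement=arrangement
            )
            vals += [wire_purchase(w, sp.epiphysis) for w in pattern.wires]
        out[tag] = vals
    np.testing.assert_allclose(out["left"], out["right"], atol=1e-6)
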