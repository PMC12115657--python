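"""Virtual Kirschner-wire trajectory planning.

Three parallel 1.6 mm wires are placed along a central trajectory running
from the third-trochanter region of the lateral cortex through the thickest
point of the capital epiphysis, in either a linear or a triangular
arrangement with 2 mm axis-to-axis spacing.  Each wire tip is set back 2 mm
(along the wire axis) from the subchondral bone margin so that, by
construction, no wire penetrates the articular surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .anatomy import LandmarkSet
from .errors import GeometryError, PlacementError
from .geometry import SUBCHONDRAL, BoneSurface, ray_mesh_intersections, unit

log = logging.getLogger(__name__)

LINEAR = "linear"
TRIANGULAR = "triangular"


@dataclass
class Wire:
    """One virtual Kirschner wire (a finite cylinder's axis)."""

    index: int
    diameter: float
    tip: np.ndarray
    entry: np.ndarray
    axis: np.ndarray
    pattern: str

    def __post_init__(self):
        self.tip = np.asarray(self.tip, dtype=float)
        self.entry = np.asarray(self.entry, dtype=float)
        self.axis = unit(self.axis)
        if self.diameter <= 0:
            raise GeometryError("wire diameter must be positive")
        if np.linalg.norm(self.tip - self.entry) < 1e-9:
            raise GeometryError("wire tip and entry coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.tip - self.entry))

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "pattern": self.pattern,
            "diameter_mm": self.diameter,
            "entry": self.entry.tolist(),
            "tip": self.tip.tolist(),
            "axis": self.axis.tolist(),
        }


@dataclass
class WirePattern:
    """Three parallel wires in a named arrangement."""

    arrangement: str
    wires: List[Wire]
    spacing: float
    tip_setback: float
    central_axis: Tuple[np.ndarray, np.ndarray]

    def __post_init__(self):
        if len(self.wires) != 3:
            raise GeometryError("a pattern holds exactly 3 wires")

    def check_invariants(self, epiphysis: BoneSurface, tol_setback: float = 0.05):
        """Assert parallelism, spacing and tip setback on a finished pattern."""
        axes = np.stack([w.axis for w in self.wires])
        if not np.all(axes @ axes.T > 1 - 1e-9):
            raise GeometryError("wire axes are not parallel")
        d = axes[0]
        pairs = ((0, 1), (1, 2)) if self.arrangement == LINEAR else ((0, 1), (1, 2), (0, 2))
        for a, b in pairs:
            offset = self.wires[a].tip - self.wires[b].tip
            lateral = offset - np.dot(offset, d) * d
            if abs(np.linalg.norm(lateral) - self.spacing) > 1e-6:
                raise GeometryError("adjacent axis-to-axis spacing violated")
        for w in self.wires:
            dist = _setback_distance(w, epiphysis)
            if abs(dist - self.tip_setback) > tol_setback:
                raise GeometryError(
                    f"wire {w.index} setback {dist:.3f} != {self.tip_setback}"
                )


def central_trajectory(
    landmarks: LandmarkSet, target
) -> Tuple[np.ndarray, np.ndarray]:
    """Trajectory from the third trochanter through the max-thickness point.

    Warns (without failing) when the direction is not simultaneously
    cranial, medial and proximal, the orientation the approach calls for.
    """
    start = np.asarray(landmarks.third_trochanter, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.linalg.norm(target - start) < 1e-9:
        raise GeometryError("trajectory endpoints coincide")
    direction = unit(target - start)
    components = {
        "cranial": float(direction @ landmarks.cranial),
        "medial": float(direction @ landmarks.medial),
        "proximal": float(direction @ landmarks.proximal),
    }
    if not all(v > 0 for v in components.values()):
        log.warning(
            "trajectory is not craniomedially-proximally directed: %s", components
        )
    return start, direction


def pattern_offsets(
    arrangement: str,
    spacing: float,
    direction,
    landmarks: LandmarkSet,
) -> np.ndarray:
    """In-plane offsets (one per wire, ordered by wire index) for a pattern.

    Offsets live in the plane perpendicular to the trajectory, spanned by
    ``u`` (projection of the proximal axis) and ``c`` (projection of the
    cranial axis, orthonormalized against ``u``).  Linear: wires 1..3 at
    ``+s*u, 0, -s*u`` (proximal to distal).  Triangular: an equilateral
    triangle of side ``s`` centered on the axis with wire 1 proximal and
    wires 2/3 craniodistal/caudodistal.
    """
    if spacing < 0:
        raise GeometryError("spacing must be >= 0")
    if arrangement not in (LINEAR, TRIANGULAR):
        raise GeometryError(f"unknown arrangement '{arrangement}'")
    d = unit(direction)
    proj_u = landmarks.proximal - (landmarks.proximal @ d) * d
    if np.linalg.norm(proj_u) < 1e-9:
        raise GeometryError("trajectory parallel to the proximal axis")
    u = unit(proj_u)
    proj_c = landmarks.cranial - (landmarks.cranial @ d) * d
    proj_c = proj_c - (proj_c @ u) * u
    if np.linalg.norm(proj_c) < 1e-9:
        raise GeometryError("cranial axis degenerate in the offset plane")
    c = unit(proj_c)
    s = float(spacing)
    if arrangement == LINEAR:
        return np.stack([s * u, 0.0 * u, -s * u])
    R = s / math.sqrt(3.0)  # circumradius of an equilateral triangle of side s
    return np.stack(
        [
            R * u,
            R * (-0.5 * u + (math.sqrt(3) / 2) * c),
            R * (-0.5 * u - (math.sqrt(3) / 2) * c),
        ]
    )


def _subchondral_hits(epiphysis: BoneSurface, origin, direction):
    mask = epiphysis.label_mask(SUBCHONDRAL)
    _, t, _ = ray_mesh_intersections(
        epiphysis.mesh, origin[None], direction[None], face_mask=mask
    )
    return t


def _setback_distance(wire: Wire, epiphysis: BoneSurface) -> float:
    """Distance from tip to the last subchondral crossing along the axis."""
    back = wire.tip - 1000.0 * wire.axis
    t = _subchondral_hits(epiphysis, back, wire.axis)
    if len(t) == 0:
        return math.inf
    return float(t.max() - 1000.0)


def place_pattern(
    epiphysis: BoneSurface,
    remainder: BoneSurface,
    trajectory: Tuple[np.ndarray, np.ndarray],
    offsets: np.ndarray,
    diameter: float = 1.6,
    tip_setback: float = 2.0,
    arrangement: str = None,
) -> WirePattern:
    """Place three parallel wires; raises if any line misses the epiphysis.

    The tip of each wire sits ``tip_setback`` mm (along the axis) short of
    the last subchondral intersection of its line, i.e. tucked beneath the
    articular dome; the entry is the first intersection of the line with
    the femur remainder (the lateral cortex).
    """
    start, d = np.asarray(trajectory[0], dtype=float), unit(trajectory[1])
    offsets = np.asarray(offsets, dtype=float)
    if arrangement is None:
        arrangement = LINEAR if np.linalg.norm(offsets[1]) < 1e-12 else TRIANGULAR

    wires, missed = [], []
    for i, offset in enumerate(offsets, start=1):
        origin = start + offset - 5.0 * d  # begin outside the lateral cortex
        t_sub = _subchondral_hits(epiphysis, origin, d)
        if len(t_sub) == 0:
            missed.append(i)
            continue
        tip = origin + (t_sub.max() - tip_setback) * d
        _, t_rem, _ = ray_mesh_intersections(remainder.mesh, origin[None], d[None])
        if len(t_rem) == 0:
            missed.append(i)
            continue
        entry = origin + t_rem.min() * d
        wires.append(
            Wire(
                index=i,
                diameter=diameter,
                tip=tip,
                entry=entry,
                axis=d,
                pattern=arrangement,
            )
        )
    if missed:
        raise PlacementError(
            f"wires {missed} missed the target surface", missed=missed
        )
    return WirePattern(
        arrangement=arrangement,
        wires=wires,
        spacing=float(np.linalg.norm(offsets[0] - offsets[1])),
        tip_setback=tip_setback,
        central_axis=(start, d),
    )


def detect_penetration(wire: Wire, epiphysis: BoneSurface):
    """Articular-penetration check: has the tip passed the subchondral margin?

    Returns ``(flag, overshoot_mm)``; overshoot is the signed distance from
    the tip past the last subchondral crossing along the wire axis, clamped
    at zero (a tip exactly on the surface does not count as penetration).
    """
    dist = _setback_distance(wire, epiphysis)
    if not math.isfinite(dist):
        raise GeometryError("wire line does not cross the subchondral surface")
    overshoot = max(0.0, -dist)
    if overshoot <= 1e-9:  # boundary contact is not penetration
        return False, 0.0
    return True, overshoot
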