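"""Per-wire epiphyseal purchase and engagement metrics.

Purchase is the length of a wire's axis segment (entry to tip) lying inside
the epiphysis solid, computed by summing inside intervals between sorted
line-mesh intersections.  The engagement ratio divides purchase by the
maximal epiphyseal thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .errors import DataError, GeometryError, ParameterError
from .geometry import BoneSurface, segment_inside_intervals
from .planner import Wire

log = logging.getLogger(__name__)

WIRE_INDICES = (1, 2, 3)


def wire_purchase(wire: Wire, epiphysis: BoneSurface) -> float:
    """Axial length (mm) of the wire seated within the epiphysis."""
    if not epiphysis.is_watertight:
        raise GeometryError("purchase requires a watertight epiphysis")
    intervals = segment_inside_intervals(epiphysis.mesh, wire.entry, wire.tip)
    return float(sum(hi - lo for lo, hi in intervals))


def engagement_ratio(purchase: float, max_thickness: float) -> float:
    """Purchase divided by maximal epiphyseal thickness (dimensionless)."""
    if max_thickness <= 0:
        raise ParameterError("max_thickness must be > 0")
    ratio = purchase / max_thickness
    if ratio > 1.0:
        log.warning("engagement ratio %.3f exceeds 1 (oblique chord)", ratio)
    return ratio


@dataclass
class PurchaseRecord:
    """Purchase and engagement of one wire in one arrangement."""

    specimen_id: str
    arrangement: str
    wire_index: int
    purchase: float
    engagement_ratio: float
    max_thickness: float

    def __post_init__(self):
        if self.purchase < 0:
            raise DataError("purchase must be >= 0")
        if self.max_thickness <= 0:
            raise DataError("max_thickness must be > 0")


@dataclass
class SpecimenResult:
    """Paired triangular-minus-linear comparison for one specimen."""

    specimen_id: str
    records: List[PurchaseRecord]
    differences: Dict[int, float]
    cumulative_difference: float
    max_thickness: float


def measure_pattern(
    specimen_id: str, pattern, epiphysis: BoneSurface, max_thickness: float
) -> List[PurchaseRecord]:
    """Purchase records (wires 1-3) for one placed pattern."""
    records = []
    for wire in pattern.wires:
        p = wire_purchase(wire, epiphysis)
        records.append(
            PurchaseRecord(
                specimen_id=specimen_id,
                arrangement=pattern.arrangement,
                wire_index=wire.index,
                purchase=p,
                engagement_ratio=engagement_ratio(p, max_thickness),
                max_thickness=max_thickness,
            )
        )
    return records


def specimen_compare(
    linear_records: List[PurchaseRecord],
    triangular_records: List[PurchaseRecord],
) -> SpecimenResult:
    """Per-wire and cumulative triangular-minus-linear purchase differences."""
    lin = {r.wire_index: r for r in linear_records}
    tri = {r.wire_index: r for r in triangular_records}
    for idx in WIRE_INDICES:
        if idx not in lin or idx not in tri:
            raise DataError(f"missing wire index {idx} in one arrangement")
    specimen_id = linear_records[0].specimen_id
    differences = {
        idx: tri[idx].purchase - lin[idx].purchase for idx in WIRE_INDICES
    }
    return SpecimenResult(
        specimen_id=specimen_id,
        records=list(linear_records) + list(triangular_records),
        differences=differences,
        cumulative_difference=sum(differences.values()),
        max_thickness=linear_records[0].max_thickness,
    )


def records_frame(results: List[SpecimenResult]):
    """All purchase records as a tidy DataFrame."""
    import pandas as pd

    rows = [
        {
            "specimen_id": r.specimen_id,
            "arrangement": r.arrangement,
            "wire_index": r.wire_index,
            "purchase_mm": round(r.purchase, 2),
            "engagement_ratio": round(r.engagement_ratio, 4),
            "max_thickness_mm": round(r.max_thickness, 2),
        }
        for res in results
        for r in res.records
    ]
    return pd.DataFrame(rows)
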