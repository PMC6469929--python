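"""Interface-geometry classification and shape/alignment indices.

After fusion, the new A/P-oriented interfaces between cells of the two
flanks remodel from straight "en-face" contacts into angled interfaces
terminating in Y-shaped tricellular vertices — the interlocked
configuration that stitches the seam together.  This module classifies
interface geometries (angular / straight / curved), detects interlocking
and interlocking-defective compartments, and computes the seam alignment
angle and leading-edge cell aspect ratios.

Coordinate convention: x increases anterior→posterior (the A/P axis), y
runs across the midline (D/V); angles are measured against x and always
reported as acute values in [0°, 90°].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fusefid.datamodel import CompartmentSnapshot, InterfaceRecord

#: Segments whose stripes are eligible for interface classification.
ELIGIBLE_SEGMENTS = ("T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6")

#: Compartments never assessed for interlocking defects (peripheral, poorly
#: visible in a dorsal-up view).
UNASSESSABLE_SEGMENTS = ("Lb", "A7")


def chord_angle(polyline) -> float:
    """Acute angle (degrees) between the endpoint chord and the A/P axis.

    Invariant to polyline orientation, translation, and reflection about
    either axis.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("chord_angle needs at least two points")
    dx, dy = pts[-1] - pts[0]
    if dx == 0 and dy == 0:
        raise ValueError("degenerate chord: endpoints coincide")
    return math.degrees(math.atan2(abs(dy), abs(dx)))


@dataclass
class GeometryLabel:
    """Classification of one interface: angular, straight, curved or ineligible."""

    label: str
    reason: str = ""


def classify_interface(
    rec: InterfaceRecord,
    sinuosity_threshold: float = 1.05,
    angle_split: float = 20.0,
) -> GeometryLabel:
    """Assign exactly one geometry class to an interface.

    Eligibility requires a length of at least 1 µm, an interface that
    connects two D/V interfaces, and a segment in T2–A6.  Eligible
    interfaces are *curved* when visibly sinuous (polyline length / chord
    length above ``sinuosity_threshold``, or a manual curved flag),
    *angular* when the chord subtends [``angle_split``, 90°] to the A/P
    axis, and *straight* below ``angle_split``.  The printed class bins
    share the 20° boundary; it is resolved here by closing the angular bin
    from below (configurable via ``angle_split``).
    """
    if rec.length_um < 1.0:
        return GeometryLabel("ineligible", f"length {rec.length_um:.3g} µm < 1 µm")
    if not rec.connects_two_DV:
        return GeometryLabel("ineligible", "does not connect two D/V interfaces")
    if rec.segment_id not in ELIGIBLE_SEGMENTS:
        return GeometryLabel("ineligible", f"segment {rec.segment_id} outside T2–A6")
    if rec.curved_flag is True or (rec.curved_flag is None and rec.sinuosity > sinuosity_threshold):
        return GeometryLabel("curved", f"sinuosity {rec.sinuosity:.3f}")
    angle = chord_angle(rec.polyline)
    if angle >= angle_split:
        return GeometryLabel("angular", f"chord angle {angle:.1f}°")
    return GeometryLabel("straight", f"chord angle {angle:.1f}°")


def mean_interface_angle(records, sinuosity_threshold: float = 1.05):
    """Mean chord angle ± s.e.m. over eligible interfaces.

    Curved interfaces still contribute their endpoint-chord angle; only
    ineligible records are excluded.  With a single record the s.e.m. is
    reported as NaN.
    """
    angles = [
        chord_angle(r.polyline)
        for r in records
        if classify_interface(r, sinuosity_threshold).label != "ineligible"
    ]
    if not angles:
        raise ValueError("no eligible interfaces to average")
    angles = np.array(angles)
    sem = float(np.std(angles, ddof=1) / math.sqrt(angles.size)) if angles.size > 1 else math.nan
    return float(np.mean(angles)), sem


def interlocked(vertex_degrees, label: GeometryLabel) -> bool:
    """Whether an interface is in the interlocked (Y-vertex) configuration.

    Operationalized as: classified angular, with both endpoints being
    tricellular (vertex degree exactly 3).
    """
    a, b = vertex_degrees
    return label.label == "angular" and a == 3 and b == 3


def interlocking_defective(snap: CompartmentSnapshot):
    """Classify a compartment snapshot as interlocking defective.

    Returns ``True``/``False``, or ``None`` when the compartment is not
    assessable: segments Lb and A7 are never assessed; during closure only
    compartments at least 10 cells from a canthus qualify; post closure the
    central-most compartment is excluded.  A compartment is defective when
    at least 70% of its cells (scored on one side of the midline) lack an
    interlocked interface.
    """
    snap.validate()
    if snap.segment_id in UNASSESSABLE_SEGMENTS:
        return None
    if snap.stage == "closure" and snap.distance_from_canthus_cells < 10:
        return None
    if snap.stage == "post_closure" and snap.is_central_most:
        return None
    lacking = sum(1 for c in snap.cells if not c.has_interlocked_interface)
    return lacking / len(snap.cells) >= 0.70


def alignment_index(boundary_upper, boundary_lower) -> float:
    """Seam alignment angle θ = |90° − α| of a contralateral boundary pair.

    α is the acute angle between the line joining the two anterior stripe
    boundaries (one on each flank) and the A/P axis.  Perfectly registered
    boundaries sit on a line perpendicular to the A/P axis, giving θ = 0.
    Symmetric in its two arguments.
    """
    p, q = np.asarray(boundary_upper, float), np.asarray(boundary_lower, float)
    if np.allclose(p, q):
        raise ValueError("boundary anchor points coincide")
    alpha = chord_angle([p, q])
    return abs(90.0 - alpha)


def aspect_ratio(dv_length: float, ap_length: float) -> float:
    """Cell aspect ratio, D/V length over A/P length."""
    if dv_length <= 0 or ap_length <= 0:
        raise ValueError("cell lengths must be positive")
    return dv_length / ap_length


def high_ar_fraction(cells, cutoff: float = 6.0) -> float:
    """Fraction of cells with aspect ratio at or above ``cutoff``."""
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell list")
    ratios = [aspect_ratio(c.dv_length, c.ap_length) for c in cells]
    return sum(r >= cutoff for r in ratios) / len(ratios)
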