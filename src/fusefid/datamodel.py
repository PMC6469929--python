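"""Shared tabular schemas, units and timeline conventions.

All lengths are in micrometres, all times in minutes, all angles in degrees.
Time is *retrospective* by convention: 0 marks completion of closure and
frames before completion are negative (so the onset of zippering sits at
about -100 min and the first analyzable frame at about -190 min).

Two sampling grids coexist, mirroring how the measurements are made: arc
lengths and fusing-front widths are traced at every movie frame (default
1 min apart), while leading-edge (DME) cell counts are taken at 5-min
intervals.  Missing measurements (e.g. peripheral compartments before they
become visible in a dorsal-up view) are stored as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SEGMENT_IDS = ("Lb", "T1", "T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8")
COMPARTMENTS = ("stripe", "interstripe")
SIDES = ("upper", "lower")
MARKERS = ("ecadherin", "actin", "myosin", "bazooka", "vinculin")
INTENSITY_STAGES = ("pre_fusion", "en_face", "interlocked")
INTERFACE_STAGES = ("pre_fusion", "en_face", "post_fusion")
EVENT_SOURCES = ("mixer_cell", "posterior_intercalating_cell")


class ValidationError(ValueError):
    """A dataset or record violates a schema invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class TimelineConvention:
    """Retrospective timeline bookkeeping for one embryo.

    Parameters
    ----------
    t_completion : float
        Retrospective time of completion of closure (0 by definition once
        the dataset is on the retrospective axis).
    t_E : float
        Earliest analyzable frame ("beginning of dorsal closure").
    t_F_by_compartment : dict
        Fusion time of each ``(segment_id, compartment)`` pair, minutes.
    frame_interval_length : float
        Spacing of the length/width tracing grid, minutes.
    frame_interval_count : float
        Spacing of the cell-count grid, minutes (default 5).
    """

    t_E: float = -190.0
    t_completion: float = 0.0
    t_F_by_compartment: dict = field(default_factory=dict)
    frame_interval_length: float = 1.0
    frame_interval_count: float = 5.0

    def validate(self) -> None:
        if self.frame_interval_length <= 0 or self.frame_interval_count <= 0:
            raise ValidationError("frame intervals must be positive")
        ratio = self.frame_interval_count / self.frame_interval_length
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                "frame_interval_count must be an integer multiple of "
                f"frame_interval_length (got {self.frame_interval_count}/"
                f"{self.frame_interval_length})"
            )
        for key, t_f in self.t_F_by_compartment.items():
            if not (self.t_E - 1e-9 <= t_f <= self.t_completion + 1e-9):
                raise ValidationError(
                    f"fusion time {t_f} of {key} outside [t_E, completion] = "
                    f"[{self.t_E}, {self.t_completion}]"
                )

    def t_F(self, segment_id: str, compartment: str = "stripe") -> float:
        """Fusion time of a compartment pair."""
        return self.t_F_by_compartment[(segment_id, compartment)]

    def t_minus(self, segment_id: str, compartment: str = "stripe", delta: float = 100.0) -> float:
        """Time ``delta`` minutes before fusion of a compartment (t_-100 etc.)."""
        return self.t_F(segment_id, compartment) - delta


@dataclass
class FlankTrack:
    """Whole-arc time series for one epidermal flank.

    ``t_L``/``L`` hold the arc-length tracing (canthus to canthus, µm, every
    frame); ``t_N``/``N`` hold the total DME cell count on the 5-min grid.
    ``replicate_L`` optionally keeps the individual repeated tracings per
    frame (shape ``(n_frames, n_replicates)``); the stored ``L`` is then
    their arithmetic mean.
    """

    side: str
    t_L: np.ndarray
    L: np.ndarray
    t_N: np.ndarray
    N: np.ndarray
    replicate_L: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_L = _as_float_array(self.t_L, "t_L")
        self.L = _as_float_array(self.L, "L")
        self.t_N = _as_float_array(self.t_N, "t_N")
        self.N = _as_float_array(self.N, "N")
        if self.replicate_L is not None:
            self.replicate_L = np.asarray(self.replicate_L, dtype=float)

    def validate(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.t_L.shape != self.L.shape or self.t_N.shape != self.N.shape:
            raise ValidationError("time and value arrays must have matching shapes")
        vis = ~np.isnan(self.L)
        if np.any(self.L[vis] <= 0):
            raise ValidationError(f"arc length must be positive on visible frames (side={self.side})")
        visn = ~np.isnan(self.N)
        if np.any(self.N[visn] < 0):
            raise ValidationError("DME cell count must be non-negative")
        if self.replicate_L is not None:
            if self.replicate_L.shape[0] != self.L.size:
                raise ValidationError("replicate_L rows must match the length grid")
            means = np.nanmean(self.replicate_L, axis=1)
            stored = self.L
            ok = np.isnan(stored) | np.isclose(means, stored, rtol=0, atol=1e-9)
            if not np.all(ok):
                raise ValidationError("stored L must equal the mean of replicate tracings")


@dataclass
class CompartmentTrack:
    """Fusing-front width and DME count for one segment compartment, one side."""

    segment_id: str
    compartment: str
    side: str
    t_W: np.ndarray
    W: np.ndarray
    t_n: np.ndarray
    n: np.ndarray
    visible_from: float = -np.inf

    def __post_init__(self) -> None:
        self.t_W = _as_float_array(self.t_W, "t_W")
        self.W = _as_float_array(self.W, "W")
        self.t_n = _as_float_array(self.t_n, "t_n")
        self.n = _as_float_array(self.n, "n")

    def validate(self) -> None:
        if self.segment_id not in SEGMENT_IDS:
            raise ValidationError(f"unknown segment_id {self.segment_id!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        vis = ~np.isnan(self.W)
        if np.any(self.W[vis] <= 0):
            raise ValidationError(
                f"nonpositive width in {self.segment_id}/{self.compartment}/{self.side}"
            )
        # frames before visible_from must be missing, never zero-filled
        early = self.t_W < self.visible_from - 1e-9
        if np.any(~np.isnan(self.W[early])):
            raise ValidationError("measurements before visible_from must be missing (NaN)")
        visn = ~np.isnan(self.n)
        if np.any(self.n[visn] < 1):
            raise ValidationError(
                f"DME count below 1 on a visible frame in {self.segment_id}/{self.compartment}"
            )

    @property
    def pair_key(self):
        return (self.segment_id, self.compartment)


@dataclass
class InterfaceRecord:
    """One fused/fusing A/P-oriented cell interface.

    ``polyline`` is an ordered array of 2-D points in µm with x along the
    A/P axis and y along the D/V axis.  ``angle_deg`` is the acute angle of
    the endpoint chord to the A/P axis; ``length_um`` is the arc length
    along the polyline.  ``curved_flag``, when set, records a manual
    "curved/squiggly" call that overrides the sinuosity rule.
    """

    embryo_id: str
    segment_id: str
    compartment: str
    t: float
    polyline: np.ndarray
    endpoint_vertex_degrees: tuple
    connects_two_DV: bool
    stage: str = "post_fusion"
    curved_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.endpoint_vertex_degrees = tuple(int(d) for d in self.endpoint_vertex_degrees)

    def validate(self) -> None:
        if self.segment_id not in SEGMENT_IDS:
            raise ValidationError(f"unknown segment_id {self.segment_id!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if self.stage not in INTERFACE_STAGES:
            raise ValidationError(f"unknown interface stage {self.stage!r}")
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2 or self.polyline.shape[0] < 2:
            raise ValidationError("polyline must be an (n>=2, 2) array of points")
        if len(self.endpoint_vertex_degrees) != 2 or any(
            d < 2 for d in self.endpoint_vertex_degrees
        ):
            raise ValidationError("endpoint vertex degrees must be a pair of integers >= 2")

    @property
    def chord_length(self) -> float:
        return float(np.hypot(*(self.polyline[-1] - self.polyline[0])))

    @property
    def length_um(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.polyline, axis=0).T)))

    @property
    def sinuosity(self) -> float:
        chord = self.chord_length
        if chord == 0:
            raise ValidationError("degenerate interface: coincident endpoints")
        return self.length_um / chord


@dataclass
class AdditionEvent:
    """One cell-addition event at a stripe's leading edge."""

    embryo_id: str
    segment_id: str
    side: str
    t_event: float
    source: str
    delta_n: int = 1

    def validate(self) -> None:
        if self.segment_id not in SEGMENT_IDS:
            raise ValidationError(f"unknown segment_id {self.segment_id!r} in event")
        if self.side not in SIDES + ("both",):
            raise ValidationError(f"unknown event side {self.side!r}")
        if self.source not in EVENT_SOURCES:
            raise ValidationError(f"unknown event source {self.source!r}")
        if self.delta_n < 1:
            raise ValidationError("delta_n must be >= 1")


@dataclass
class IntensityRecord:
    """Mean junctional fluorescence with its D/V-interface reference.

    ``I`` is the mean intensity along fused/fusing A/P interfaces; ``I_DV``
    the mean along D/V-oriented interfaces of the same cells, used for
    normalization.  ``n_interfaces`` is the size of the averaging set
    (10 cells for the adhesion marker, 5 for cytoskeletal markers, by the
    measurement convention).
    """

    embryo_id: str
    marker: str
    stage: str
    I: float
    I_DV: float
    n_interfaces: int

    def validate(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        if self.stage not in INTENSITY_STAGES:
            raise ValidationError(f"unknown intensity stage {self.stage!r}")
        if self.I < 0:
            raise ValidationError("intensity I must be >= 0")
        if self.I_DV <= 0:
            raise ValidationError("reference intensity I_DV must be > 0")
        if self.n_interfaces < 1:
            raise ValidationError("n_interfaces must be >= 1")


@dataclass
class CellEntry:
    """One DME cell inside a compartment snapshot."""

    has_interlocked_interface: bool
    dv_length: float
    ap_length: float

    def validate(self) -> None:
        if self.dv_length <= 0 or self.ap_length <= 0:
            raise ValidationError("cell D/V and A/P lengths must be positive")


@dataclass
class CompartmentSnapshot:
    """Per-cell interlocking/shape snapshot of one compartment, one side."""

    embryo_id: str
    segment_id: str
    compartment: str
    cells: list
    stage: str = "post_closure"
    distance_from_canthus_cells: int = 10
    is_central_most: bool = False

    def validate(self) -> None:
        if self.segment_id not in SEGMENT_IDS:
            raise ValidationError(f"unknown segment_id {self.segment_id!r} in snapshot")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if self.stage not in ("closure", "post_closure"):
            raise ValidationError(f"unknown snapshot stage {self.stage!r}")
        if not self.cells:
            raise ValidationError("snapshot has an empty cell list")
        for c in self.cells:
            c.validate()


@dataclass
class EmbryoDataset:
    """All tracked tables for one embryo; the unit of analysis."""

    embryo_id: str
    genotype_label: str
    timeline: TimelineConvention
    flanks: list
    compartments: list = field(default_factory=list)
    interfaces: list = field(default_factory=list)
    events: list = field(default_factory=list)
    intensities: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.timeline.validate()
        sides = sorted(f.side for f in self.flanks)
        if sides != ["lower", "upper"]:
            raise ValidationError(
                f"dataset must have exactly one upper and one lower flank, got {sides}"
            )
        for f in self.flanks:
            f.validate()
        known = set()
        for c in self.compartments:
            c.validate()
            known.add(c.segment_id)
        for rec in self.interfaces:
            rec.validate()
            if rec.segment_id not in known:
                raise ValidationError(
                    f"interface references segment {rec.segment_id!r} with no compartment track"
                )
        for ev in self.events:
            ev.validate()
            if ev.segment_id not in known:
                raise ValidationError(
                    f"event references segment {ev.segment_id!r} with no compartment track"
                )
        for rec in self.intensities:
            rec.validate()
        for snap in self.snapshots:
            snap.validate()
        for (seg, _comp) in self.timeline.t_F_by_compartment:
            if seg not in known:
                raise ValidationError(
                    f"fusion time references segment {seg!r} with no compartment track"
                )

    def flank(self, side: str) -> FlankTrack:
        for f in self.flanks:
            if f.side == side:
                return f
        raise KeyError(side)

    def compartment(self, segment_id: str, compartment: str, side: str) -> CompartmentTrack:
        for c in self.compartments:
            if (c.segment_id, c.compartment, c.side) == (segment_id, compartment, side):
                return c
        raise KeyError((segment_id, compartment, side))
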