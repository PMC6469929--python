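"""Seeded generative model of tracked dorsal-closure measurements.

The generator is phenomenological at the *measurement* level: it does not
simulate tissue mechanics, it emits the tables a tracking session would —
arc-length and DME-count time series for both flanks, per-compartment
width/count tracks, cell-addition event logs, interface records with
polylines and vertex degrees, per-cell interlocking snapshots and
intensity records — together with ground-truth labels for every quantity a
downstream classifier or detector estimates.

Three modes reproduce the study conditions:

``control``
    Flank disparities decay to near zero well before completion (arc
    length by about −100 min, whole-arc cell count by −50 min, via
    scheduled discrete cell additions); en-face contacts interlock with a
    mean delay of ~15.9 min after fusion; junctional actin clears ~10.9
    min after fusion while the polarity protein Bazooka is recruited with
    an ~11.2 min delay and peaks at interlocking.
``tension_deficient``
    Disparities are statistically invariant over time, fusion of the
    peripheral segments is delayed, interfaces stay straight or curved and
    at least 70% of cells per compartment lack interlocked interfaces.
``baz_deficient``
    Bazooka recruitment and interlocking are delayed (~24.6 min), fused
    interfaces are frequently curved with a reduced mean chord angle
    (32.3° vs 39.7°), junctional actin persists ≥20 min after fusion, and
    the probability of a two-cell disparity at fusion rises.

Identical (seed, config) pairs produce byte-identical serialized output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from fusefid.datamodel import (
    AdditionEvent,
    CellEntry,
    CompartmentSnapshot,
    CompartmentTrack,
    EmbryoDataset,
    FlankTrack,
    IntensityRecord,
    InterfaceRecord,
    TimelineConvention,
)

MODES = ("control", "tension_deficient", "baz_deficient")


@dataclass
class SimulationConfig:
    """Parameters of the generative model (times in minutes, lengths in µm)."""

    seed: int = 0
    n_embryos: int = 16
    mode: str = "control"

    #: Fusion chronology (retrospective minutes) of the tracked segments:
    #: peripheral Lb/A7 fuse ~30 min after the first analyzable frame,
    #: zippering starts at −100 and the central-most segment fuses last.
    chronology: dict = field(default_factory=lambda: {
        "Lb": -130.0, "A7": -130.0, "T2": -75.0, "A4": -45.0, "A2": -20.0, "A3": 0.0,
    })
    #: In the tension-deficient mode peripheral fusion is delayed by this much.
    tension_fusion_delay: float = 20.0

    t_E: float = -190.0
    frame_interval_length: float = 1.0
    frame_interval_count: float = 5.0

    # whole-arc geometry
    arc_length_initial: float = 350.0
    arc_length_final: float = 40.0
    #: Configured arc-length and whole-arc count equalization times.
    t_len_eq: float = -100.0
    t_count_eq: float = -50.0
    #: Arc-length disparity ramps down to zero over this many minutes before t_len_eq.
    len_eq_ramp: float = 15.0
    arc_disparity_range: tuple = (0.10, 0.20)
    arc_n_base: int = 60
    arc_delta_n_range: tuple = (2, 4)

    # compartments
    stripe_n_base: tuple = (4, 6)        # stripes have ~half the DME cells
    interstripe_n_base: tuple = (9, 12)  # of interstripes
    stripe_w0: float = 15.0
    stripe_wf: float = 12.0
    interstripe_w0: float = 30.0
    interstripe_wf: float = 25.0
    width_disparity_range: tuple = (0.10, 0.25)
    width_relax_tau: float = 40.0
    peripheral_visible_delay: float = 30.0

    #: ΔDME distribution over {0, 1, 2} at the start of a stripe pair's window.
    p_delta_initial: tuple = (0.25, 0.50, 0.25)
    #: ΔDME distribution at fusion; control per the observed 46.2% one-cell
    #: disparity and no two-cell pairs; the deficient mode shifts mass to 2.
    p_delta_fusion: dict = field(default_factory=lambda: {
        "control": (0.538, 0.462, 0.0),
        "tension_deficient": (0.30, 0.50, 0.20),
        "baz_deficient": (0.374, 0.46, 0.166),
    })
    p_type2_event: float = 0.4
    p_other_event: float = 0.15
    p_source_mixer: float = 0.5

    # interface kinetics (means; sd reconstructed from the reported sem·√n)
    bazooka_recruitment_delay: float = 11.2
    interlock_time: float = 15.9
    interlock_time_baz_deficient: float = 24.6
    interlock_time_sd: float = 7.7
    actin_clearance_time: float = 10.9
    actin_clearance_sd: float = 2.0
    mean_interface_angle: float = 39.7
    mean_interface_angle_baz_deficient: float = 32.3
    interface_angle_sd: float = 5.0
    curved_sinuosity: float = 1.15
    p_curved_baz_deficient: float = 0.6
    interfaces_per_compartment: int = 5
    post_fusion_observation: float = 30.0

    # snapshots: (cells per compartment, cells lacking interlocked interfaces)
    snapshot_cells: int = 10
    snapshot_lacking: dict = field(default_factory=lambda: {
        "control": 1, "tension_deficient": 9, "baz_deficient": 8,
    })
    snapshot_high_ar_cells: dict = field(default_factory=lambda: {
        "control": 0, "tension_deficient": 1, "baz_deficient": 3,
    })

    # measurement noise: multiplicative Gaussian on length/width tracings,
    # averaged over replicate repeated tracings; counts are exact integers.
    noise_cv: float = 0.02
    n_replicates: int = 6
    store_replicates: bool = False
    intensity_cv: float = 0.05

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown simulation mode {self.mode!r}; pick one of {MODES}")
        for name in ("len_eq_ramp", "width_relax_tau", "interlock_time",
                     "actin_clearance_time", "bazooka_recruitment_delay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for p in (self.p_delta_initial, *self.p_delta_fusion.values()):
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("ΔDME probabilities must sum to 1")

    @property
    def effective_noise_sd(self) -> float:
        return self.noise_cv / math.sqrt(self.n_replicates)


@dataclass
class GroundTruth:
    """Generator-side truth for every downstream estimator."""

    #: embryo_id -> {"arc_length": t* or None, "dme_arc": t* or None}
    equalization: dict = field(default_factory=dict)
    #: (embryo_id, event_index) -> dict with the scheduled label and the
    #: integer inputs the classifier should reconstruct.
    event_labels: dict = field(default_factory=dict)
    #: (embryo_id, segment, compartment) -> True/False/None
    interlock_defect: dict = field(default_factory=dict)
    #: (embryo_id, segment, compartment, interface_index) -> geometry class
    geometry_class: dict = field(default_factory=dict)
    #: realized interlock completion delays (min after fusion), pooled
    interlock_times: list = field(default_factory=list)
    #: realized actin clearance delays per embryo
    actin_clearance_times: list = field(default_factory=list)
    #: embryo_id -> list of (t, side) whole-arc cell additions
    arc_additions: dict = field(default_factory=dict)
    configured_mean_angle: float = float("nan")


# ---------------------------------------------------------------------------


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (bounds are generous; cheap)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = (out < lo) | (out > hi)
    return out


def _noisy(rng, values, cfg: SimulationConfig):
    """Replicate-averaged multiplicative tracing noise on an array."""
    if cfg.noise_cv == 0:
        return np.array(values, float), None
    reps = np.asarray(values, float)[:, None] * rng.normal(
        1.0, cfg.noise_cv, size=(len(values), cfg.n_replicates)
    )
    return reps.mean(axis=1), reps


def _polyline(rng, x0, y0, angle_deg, chord, sinuosity):
    """3-point polyline with the given chord angle and target sinuosity.

    The midpoint is displaced perpendicular to the chord so that the
    polyline length is ``sinuosity`` times the chord length.
    """
    th = math.radians(angle_deg)
    sy = 1.0 if rng.random() < 0.5 else -1.0
    dx, dy = chord * math.cos(th), sy * chord * math.sin(th)
    p0 = np.array([x0, y0])
    p2 = p0 + (dx, dy)
    mid = (p0 + p2) / 2
    if sinuosity > 1.0:
        h = (chord / 2.0) * math.sqrt(sinuosity**2 - 1.0)
        normal = np.array([-dy, dx]) / chord
        mid = mid + h * normal * (1.0 if rng.random() < 0.5 else -1.0)
    return np.vstack([p0, mid, p2])


def _event_schedule(rng, cfg, delta_init, delta_fus, t_grid):
    """Build a ΔDME step path and the events realizing it.

    Returns a list of step dicts ``{t, kind, ddme_before, ddme_after}``
    with kinds in {type3, type2, other}; steps are spaced at least two
    count frames apart so before/after windows never overlap.
    """
    kinds = []
    d = delta_init
    if rng.random() < cfg.p_other_event and d < 2:
        kinds.append("other")      # one disparity-increasing addition
        d += 1
    while d > delta_fus:
        kinds.append("type3")
        d -= 1
    if rng.random() < cfg.p_type2_event:
        kinds.insert(rng.integers(0, len(kinds) + 1), "type2")
    if not kinds:
        return []
    # candidate event frames: interior of the window, spacing >= 2 frames
    interior = t_grid[1:-1]
    slots = interior[::2]
    if len(slots) < len(kinds):
        kinds = kinds[: len(slots)]
    times = np.sort(rng.choice(slots, size=len(kinds), replace=False))
    steps, d = [], delta_init
    for kind, t in zip(kinds, times):
        before = d
        if kind == "type3":
            d -= 1
        elif kind == "other":
            d += 1
        steps.append({"t": float(t), "kind": kind, "ddme_before": before, "ddme_after": d})
    return steps


def _simulate_embryo(rng, cfg: SimulationConfig, embryo_id: str, truth: GroundTruth):
    mode = cfg.mode
    chronology = dict(cfg.chronology)
    if mode == "tension_deficient":
        chronology = {
            seg: (t + cfg.tension_fusion_delay if t < 0 else t)
            for seg, t in chronology.items()
        }

    t_F_by_compartment = {
        (seg, comp): t for seg, t in chronology.items() for comp in ("stripe", "interstripe")
    }
    timeline = TimelineConvention(
        t_E=cfg.t_E,
        t_completion=0.0,
        t_F_by_compartment=t_F_by_compartment,
        frame_interval_length=cfg.frame_interval_length,
        frame_interval_count=cfg.frame_interval_count,
    )

    # ---- whole-arc tracks ------------------------------------------------
    t_L = np.arange(cfg.t_E, 0.0 + 1e-9, cfg.frame_interval_length)
    progress = (t_L - cfg.t_E) / (0.0 - cfg.t_E)
    L_bar = cfg.arc_length_initial + (cfg.arc_length_final - cfg.arc_length_initial) * progress

    d0 = rng.uniform(*cfg.arc_disparity_range) * (1 if rng.random() < 0.5 else -1)
    if mode == "tension_deficient":
        d_t = np.full_like(t_L, d0)
        truth_len_eq = None
    else:
        ramp_start = cfg.t_len_eq - cfg.len_eq_ramp
        d_t = np.where(
            t_L <= ramp_start,
            d0,
            np.where(t_L >= cfg.t_len_eq, 0.0, d0 * (cfg.t_len_eq - t_L) / cfg.len_eq_ramp),
        )
        # truth = the detector definition applied to the noise-free series
        below = np.abs(d_t) <= 0.05
        idx = np.nonzero(~below)[0]
        truth_len_eq = float(t_L[(idx[-1] + 1) if idx.size else 0])

    L_u_clean = L_bar * (1 + d_t / 2)
    L_l_clean = L_bar * (1 - d_t / 2)
    L_u, reps_u = _noisy(rng, L_u_clean, cfg)
    L_l, reps_l = _noisy(rng, L_l_clean, cfg)

    t_N = np.arange(-100.0, 0.0 + 1e-9, cfg.frame_interval_count)
    N_low0 = cfg.arc_n_base + int(rng.integers(0, 6))
    dN0 = int(rng.integers(cfg.arc_delta_n_range[0], cfg.arc_delta_n_range[1] + 1))
    upper_is_high = rng.random() < 0.5
    additions = []
    if mode != "tension_deficient" and dN0 > 0:
        # single-cell additions on the low side; the last lands exactly at
        # the configured count-equalization time
        pool = t_N[(t_N >= -95.0) & (t_N <= cfg.t_count_eq - 5.0)]
        picks = np.sort(rng.choice(pool, size=dN0 - 1, replace=False)) if dN0 > 1 else []
        additions = [float(t) for t in picks] + [cfg.t_count_eq]
    low = N_low0 + np.searchsorted(additions, t_N, side="right") if additions else np.full(
        t_N.shape, N_low0, dtype=float
    )
    high = np.full(t_N.shape, float(N_low0 + dN0))
    N_u, N_l = (high, np.asarray(low, float)) if upper_is_high else (np.asarray(low, float), high)
    low_side = "lower" if upper_is_high else "upper"
    truth.arc_additions[embryo_id] = [(t, low_side) for t in additions]
    truth_count_eq = cfg.t_count_eq if mode != "tension_deficient" else None
    truth.equalization[embryo_id] = {"arc_length": truth_len_eq, "dme_arc": truth_count_eq}

    flanks = [
        FlankTrack("upper", t_L, L_u, t_N, N_u,
                   replicate_L=reps_u if cfg.store_replicates else None),
        FlankTrack("lower", t_L, L_l, t_N, N_l,
                   replicate_L=reps_l if cfg.store_replicates else None),
    ]

    # ---- compartment tracks and addition events --------------------------
    compartments, events, event_idx = [], [], 0
    peripheral = ("Lb", "A7")
    p_fus = cfg.p_delta_fusion[mode]

    for seg, t_f in sorted(chronology.items()):
        for comp in ("stripe", "interstripe"):
            if seg in peripheral:
                visible_from = cfg.t_E + cfg.peripheral_visible_delay
                win_lo = cfg.t_E
            else:
                visible_from = -np.inf
                win_lo = max(cfg.t_E, t_f - 100.0)
            t_W = np.arange(win_lo, t_f + 1e-9, cfg.frame_interval_length)
            grid_lo = math.ceil(max(win_lo, visible_from) / cfg.frame_interval_count)
            t_n = np.arange(grid_lo * cfg.frame_interval_count, t_f + 1e-9,
                            cfg.frame_interval_count)

            base_lo, base_hi = (cfg.stripe_n_base if comp == "stripe"
                                else cfg.interstripe_n_base)
            base = int(rng.integers(base_lo, base_hi + 1))
            # draw the fusion-time disparity first so its configured
            # distribution is realized exactly; the initial disparity can
            # only be at least as large (it never worsens toward fusion)
            d_fus = int(rng.choice([0, 1, 2], p=p_fus))
            d_init = max(int(rng.choice([0, 1, 2], p=cfg.p_delta_initial)), d_fus)
            upper_low = rng.random() < 0.5

            steps = []
            if mode == "tension_deficient" or comp == "interstripe" or seg in peripheral:
                d_fus = d_init  # disparity persists; no corrective events
            else:
                steps = _event_schedule(rng, cfg, d_init, d_fus, t_n)

            add_low = np.zeros(t_n.shape)
            add_high = np.zeros(t_n.shape)
            for s in steps:
                at = t_n >= s["t"] - 1e-9
                if s["kind"] == "type3":
                    add_low[at] += 1
                    side = "upper" if upper_low else "lower"
                    added_u, added_l = (1, 0) if upper_low else (0, 1)
                elif s["kind"] == "type2":
                    add_low[at] += 1
                    add_high[at] += 1
                    side = "both"
                    added_u, added_l = 1, 1
                else:  # disparity-increasing addition on the higher-count side
                    add_high[at] += 1
                    side = "lower" if upper_low else "upper"
                    added_u, added_l = (0, 1) if upper_low else (1, 0)
                source = ("mixer_cell" if rng.random() < cfg.p_source_mixer
                          else "posterior_intercalating_cell")
                events.append(AdditionEvent(embryo_id, seg, side, s["t"], source, 1))
                lower_count_side = ("tie" if s["ddme_before"] == 0
                                    else ("upper" if upper_low else "lower"))
                truth.event_labels[(embryo_id, event_idx)] = {
                    "label": s["kind"] if s["kind"] != "other" else "other",
                    "segment_id": seg,
                    "ddme_before": s["ddme_before"],
                    "ddme_after": s["ddme_after"],
                    "added_upper": added_u,
                    "added_lower": added_l,
                    "lower_count_side": lower_count_side,
                    "t": s["t"],
                }
                event_idx += 1

            n_low = base + add_low
            n_high = base + d_init + add_high
            n_u, n_l = (n_low, n_high) if upper_low else (n_high, n_low)

            w0, wf = ((cfg.stripe_w0, cfg.stripe_wf) if comp == "stripe"
                      else (cfg.interstripe_w0, cfg.interstripe_wf))
            if mode == "baz_deficient" and comp == "stripe":
                wf *= 0.9
            prog = (t_W - t_W[0]) / max(t_W[-1] - t_W[0], 1.0)
            w_bar = w0 + (wf - w0) * prog
            dw0 = rng.uniform(*cfg.width_disparity_range) * (1 if rng.random() < 0.5 else -1)
            if mode == "tension_deficient":
                dw = np.full_like(t_W, dw0)
            else:
                dw = dw0 * np.exp(-(t_W - t_W[0]) / cfg.width_relax_tau)
                for s in steps:
                    if s["kind"] != "type3":
                        continue
                    near = np.abs(t_W - s["t"]) <= 3.0
                    after = t_W > s["t"] + 3.0
                    dw = np.where(near, dw * 0.15, dw)   # transient equalization
                    dw = np.where(after, dw * 0.5, dw)   # partially sustained
            w_u = w_bar * (1 + dw / 2) * rng.normal(1.0, cfg.effective_noise_sd, t_W.shape)
            w_l = w_bar * (1 - dw / 2) * rng.normal(1.0, cfg.effective_noise_sd, t_W.shape)
            hidden = t_W < visible_from - 1e-9
            w_u[hidden] = np.nan
            w_l[hidden] = np.nan
            n_mask = t_n < visible_from - 1e-9

            for side, w, n in (("upper", w_u, n_u), ("lower", w_l, n_l)):
                n_arr = np.array(n, float)
                n_arr[n_mask] = np.nan
                compartments.append(
                    CompartmentTrack(seg, comp, side, t_W, np.array(w), t_n, n_arr,
                                     visible_from=float(visible_from)
                                     if np.isfinite(visible_from) else -np.inf)
                )

    # ---- interfaces -------------------------------------------------------
    interfaces = []
    eligible = [s for s in chronology if s in ("T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6")]
    mean_angle = (cfg.mean_interface_angle_baz_deficient if mode == "baz_deficient"
                  else cfg.mean_interface_angle)
    interlock_mu = (cfg.interlock_time_baz_deficient if mode == "baz_deficient"
                    else cfg.interlock_time)
    for seg in sorted(eligible):
        t_f = chronology[seg]
        t_obs = t_f + cfg.post_fusion_observation
        if t_obs > 0:
            t_obs = 0.0
        for k in range(cfg.interfaces_per_compartment):
            x0 = rng.uniform(0, 100)
            chord = rng.uniform(2.0, 5.0)
            if mode == "tension_deficient":
                # interfaces never remodel: straight, non-tricellular
                angle = rng.uniform(0.0, 15.0)
                poly = _polyline(rng, x0, 0.0, angle, chord, 1.0)
                rec = InterfaceRecord(embryo_id, seg, "stripe", t_obs, poly, (4, 4),
                                      True, stage="en_face")
                klass = "angular" if angle >= 20.0 else "straight"
            else:
                t_lock = float(_trunc_normal(rng, interlock_mu, cfg.interlock_time_sd,
                                             1.0, 60.0))
                truth.interlock_times.append(t_lock)
                locked = (t_obs - t_f) >= t_lock
                curved = (mode == "baz_deficient"
                          and rng.random() < cfg.p_curved_baz_deficient)
                if locked:
                    angle = float(_trunc_normal(rng, mean_angle, cfg.interface_angle_sd,
                                                20.0, 90.0))
                    degrees = (3, 3)
                    stage = "post_fusion"
                else:
                    angle = rng.uniform(0.0, 10.0)
                    degrees = (4, 4)
                    stage = "en_face"
                sin = cfg.curved_sinuosity if curved else 1.0
                poly = _polyline(rng, x0, 0.0, angle, chord, sin)
                rec = InterfaceRecord(embryo_id, seg, "stripe", t_obs, poly, degrees,
                                      True, stage=stage)
                klass = "curved" if curved else ("angular" if angle >= 20.0 else "straight")
            interfaces.append(rec)
            truth.geometry_class[(embryo_id, seg, "stripe", k)] = klass

    # ---- interlocking snapshots -------------------------------------------
    snapshots = []
    lacking = cfg.snapshot_lacking[mode]
    high_ar = cfg.snapshot_high_ar_cells[mode]
    for seg in sorted(chronology):
        cells = []
        order = rng.permutation(cfg.snapshot_cells)
        for i in range(cfg.snapshot_cells):
            tall = order[i] < high_ar
            dv = rng.uniform(11.0, 13.0) if tall else rng.uniform(8.0, 11.0)
            ap = rng.uniform(1.6, 2.0) if tall else rng.uniform(3.5, 4.5)
            cells.append(CellEntry(
                has_interlocked_interface=bool(order[i] >= lacking
                                               if order[i] < cfg.snapshot_cells else True),
                dv_length=float(dv), ap_length=float(ap),
            ))
        snap = CompartmentSnapshot(embryo_id, seg, "stripe", cells,
                                   stage="post_closure",
                                   distance_from_canthus_cells=12,
                                   is_central_most=False)
        snapshots.append(snap)
        if seg in ("Lb", "A7"):
            truth.interlock_defect[(embryo_id, seg, "stripe")] = None
        else:
            truth.interlock_defect[(embryo_id, seg, "stripe")] = lacking / cfg.snapshot_cells >= 0.70

    # ---- intensity records -------------------------------------------------
    kinetics = {
        "control": {
            "ecadherin": (1.0, 1.2, 1.3),
            "actin": (1.8, 1.5, 0.7),
            "bazooka": (0.3, 0.9, 1.4),
        },
        "tension_deficient": {
            "ecadherin": (1.0, 1.1, 1.1),
            "actin": (1.8, 1.7, 1.6),
            "bazooka": (0.3, 0.5, 0.6),
        },
        "baz_deficient": {
            "ecadherin": (1.0, 1.1, 1.1),
            "actin": (1.8, 1.7, 1.5),
            "bazooka": (0.3, 0.4, 0.4),
        },
    }[mode]
    intensities = []
    i_dv = 100.0
    for marker, profile in kinetics.items():
        n_set = 10 if marker == "ecadherin" else 5
        for stage, level in zip(("pre_fusion", "en_face", "interlocked"), profile):
            val = i_dv * level * float(rng.normal(1.0, cfg.intensity_cv))
            intensities.append(IntensityRecord(embryo_id, marker, stage,
                                               I=max(val, 0.0), I_DV=i_dv,
                                               n_interfaces=n_set))
    clear_mu = cfg.actin_clearance_time if mode == "control" else 22.0
    truth.actin_clearance_times.append(
        float(_trunc_normal(rng, clear_mu, cfg.actin_clearance_sd, 1.0, 60.0))
    )

    return EmbryoDataset(
        embryo_id=embryo_id,
        genotype_label=mode,
        timeline=timeline,
        flanks=flanks,
        compartments=compartments,
        interfaces=interfaces,
        events=events,
        intensities=intensities,
        snapshots=snapshots,
        provenance={"generator": "fusefid.simulate", "seed": cfg.seed, "mode": mode},
    )


def simulate(config: SimulationConfig):
    """Generate ``config.n_embryos`` tracked datasets plus their ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(configured_mean_angle=(
        config.mean_interface_angle_baz_deficient if config.mode == "baz_deficient"
        else config.mean_interface_angle
    ))
    datasets = [
        _simulate_embryo(rng, config, f"{config.mode}_{i:03d}", truth)
        for i in range(config.n_embryos)
    ]
    for ds in datasets:
        ds.validate()
    return datasets, truth


# ---------------------------------------------------------------------------
# tiny hand-checkable fixtures


def make_fixture(name: str):
    """Return ``(dataset, expected)`` for a named hand-checkable fixture.

    ``expected`` maps descriptor names to their exact hand-computed values.
    """
    builders = {
        "equal_pair": _fixture_equal_pair,
        "one_cell_gap": _fixture_one_cell_gap,
        "defective_stripe": _fixture_defective_stripe,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(builders)}")
    return builders[name]()


def _base_timeline(t_f):
    return TimelineConvention(
        t_E=-45.0, t_completion=0.0,
        t_F_by_compartment={("A2", "stripe"): t_f, ("A3", "stripe"): t_f,
                            ("A2", "interstripe"): t_f, ("A3", "interstripe"): t_f},
        frame_interval_length=5.0, frame_interval_count=5.0,
    )


def _fixture_tracks(n_u, n_l, w_u, w_l):
    t = np.arange(-45.0, 0.0 + 1e-9, 5.0)
    flanks = [
        FlankTrack("upper", t, np.full(t.shape, 200.0), t, np.full(t.shape, 40.0)),
        FlankTrack("lower", t, np.full(t.shape, 200.0), t, np.full(t.shape, 40.0)),
    ]
    comps = []
    for seg in ("A2", "A3"):
        for comp in ("stripe", "interstripe"):
            for side, w, n in (("upper", w_u, n_u), ("lower", w_l, n_l)):
                comps.append(CompartmentTrack(seg, comp, side, t, np.full(t.shape, w),
                                              t, np.full(t.shape, float(n))))
    return t, flanks, comps


def _fixture_equal_pair():
    _, flanks, comps = _fixture_tracks(5, 5, 15.0, 15.0)
    ds = EmbryoDataset("fixture_equal", "control", _base_timeline(0.0), flanks, comps)
    ds.validate()
    return ds, {"norm_ddme_at_tF": 0.0, "norm_dwidth_all": 0.0,
                "constriction_index": 15.0 / 5}


def _fixture_one_cell_gap():
    # n_u = 5, n_l = 4 everywhere: ΔDME = 1, Norm.ΔDME = 1 / 4.5 = 2/9
    _, flanks, comps = _fixture_tracks(5, 4, 15.0, 15.0)
    ds = EmbryoDataset("fixture_gap", "control", _base_timeline(0.0), flanks, comps)
    ds.validate()
    return ds, {"ddme_at_tF": 1, "norm_ddme_at_tF": 2.0 / 9.0,
                "constriction_index_upper": 3.0}


def _fixture_defective_stripe():
    ds, _ = _fixture_equal_pair()
    cells = [CellEntry(False, 10.0, 4.0) for _ in range(7)] + [
        CellEntry(True, 10.0, 4.0) for _ in range(3)
    ]
    ds.snapshots.append(CompartmentSnapshot("fixture_equal", "A3", "stripe", cells,
                                            stage="post_closure",
                                            distance_from_canthus_cells=12,
                                            is_central_most=False))
    ds.validate()
    return ds, {"interlocking_defective": True, "fraction_lacking": 0.7}


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Plain-dict view of a config (for provenance/metadata serialization)."""
    return asdict(cfg)
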