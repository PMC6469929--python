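"""Reading and writing embryo datasets as plain TSV tables plus JSON metadata.

A dataset directory holds one embryo:

``flanks.tsv``
    embryo_id, side, t_min, L_um, N_cells — one row per time on the union of
    the length and count grids; ``NA`` marks a value that is off-grid or
    missing at that frame.
``flank_replicates.tsv``
    long-format repeated tracings (embryo_id, side, t_min, replicate, L_um);
    only written when replicates exist.
``compartments.tsv``
    embryo_id, segment_id, compartment, side, t_min, W_um, n_cells.
``interfaces.tsv``
    embryo_id, segment_id, compartment, t_min, stage, angle_deg, length_um,
    sinuosity, vdeg_a, vdeg_b, connects_two_DV, curved_flag, polyline
    (JSON-encoded point list).  The polyline is authoritative; angle, length
    and sinuosity are derived convenience columns.
``events.tsv``
    embryo_id, segment_id, side, t_min, source, delta_n.
``intensities.tsv``
    embryo_id, marker, stage, I, I_DV, n_interfaces.
``snapshots.tsv``
    per-cell rows of the interlocking snapshots.
``metadata.json``
    embryo_id, genotype_label, the timeline block, the exact sampling grids
    of every track (so missing-on-grid is distinguishable from off-grid),
    and simulator provenance when the dataset is synthetic.

All tables are UTF-8, tab-delimited, with a header row and ``NA`` for
missing values.
"""

from __future__ import annotations

import copy
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

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
    ValidationError,
)

_READ_KW = dict(sep="\t", na_values=["NA"], keep_default_na=False,
                float_precision="round_trip")
_WRITE_KW = dict(sep="\t", na_rep="NA", index=False, float_format="%.17g")


def replicate_average(traces) -> float:
    """Arithmetic mean of repeated tracings of one measurement.

    The mean of replicate cell counts is kept unrounded: a fractional mean
    count feeds the normalized-difference descriptors as-is.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("replicate_average requires at least one trace")
    return float(np.mean(traces))


def _grid_values(t_grid, table_t, table_v):
    """Pick values for each grid time from a (t, value) table; NaN if absent."""
    lookup = {round(float(t), 6): float(v) for t, v in zip(table_t, table_v) if not pd.isna(v)}
    return np.array([lookup.get(round(float(t), 6), math.nan) for t in t_grid])


def write_dataset(ds: EmbryoDataset, path) -> Path:
    """Serialize a validated :class:`EmbryoDataset` to a directory of TSVs."""
    ds.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for f in ds.flanks:
        t_union = np.union1d(f.t_L, f.t_N)
        lmap = dict(zip(f.t_L.tolist(), f.L.tolist()))
        nmap = dict(zip(f.t_N.tolist(), f.N.tolist()))
        for t in t_union:
            rows.append(
                {
                    "embryo_id": ds.embryo_id,
                    "side": f.side,
                    "t_min": float(t),
                    "L_um": lmap.get(float(t), math.nan),
                    "N_cells": nmap.get(float(t), math.nan),
                }
            )
    pd.DataFrame(rows, columns=["embryo_id", "side", "t_min", "L_um", "N_cells"]).to_csv(
        path / "flanks.tsv", **_WRITE_KW
    )

    rep_rows = []
    for f in ds.flanks:
        if f.replicate_L is None:
            continue
        for i, t in enumerate(f.t_L):
            for r in range(f.replicate_L.shape[1]):
                rep_rows.append(
                    {
                        "embryo_id": ds.embryo_id,
                        "side": f.side,
                        "t_min": float(t),
                        "replicate": r,
                        "L_um": float(f.replicate_L[i, r]),
                    }
                )
    if rep_rows:
        pd.DataFrame(rep_rows).to_csv(path / "flank_replicates.tsv", **_WRITE_KW)

    comp_rows = []
    for c in ds.compartments:
        t_union = np.union1d(c.t_W, c.t_n)
        wmap = dict(zip(c.t_W.tolist(), c.W.tolist()))
        nmap = dict(zip(c.t_n.tolist(), c.n.tolist()))
        for t in t_union:
            comp_rows.append(
                {
                    "embryo_id": ds.embryo_id,
                    "segment_id": c.segment_id,
                    "compartment": c.compartment,
                    "side": c.side,
                    "t_min": float(t),
                    "W_um": wmap.get(float(t), math.nan),
                    "n_cells": nmap.get(float(t), math.nan),
                }
            )
    pd.DataFrame(
        comp_rows,
        columns=["embryo_id", "segment_id", "compartment", "side", "t_min", "W_um", "n_cells"],
    ).to_csv(path / "compartments.tsv", **_WRITE_KW)

    iface_rows = []
    for rec in ds.interfaces:
        iface_rows.append(
            {
                "embryo_id": rec.embryo_id,
                "segment_id": rec.segment_id,
                "compartment": rec.compartment,
                "t_min": rec.t,
                "stage": rec.stage,
                "angle_deg": _chord_angle_of(rec.polyline),
                "length_um": rec.length_um,
                "sinuosity": rec.sinuosity,
                "vdeg_a": rec.endpoint_vertex_degrees[0],
                "vdeg_b": rec.endpoint_vertex_degrees[1],
                "connects_two_DV": rec.connects_two_DV,
                "curved_flag": "NA" if rec.curved_flag is None else rec.curved_flag,
                "polyline": json.dumps(rec.polyline.tolist()),
            }
        )
    pd.DataFrame(
        iface_rows,
        columns=[
            "embryo_id", "segment_id", "compartment", "t_min", "stage", "angle_deg",
            "length_um", "sinuosity", "vdeg_a", "vdeg_b", "connects_two_DV",
            "curved_flag", "polyline",
        ],
    ).to_csv(path / "interfaces.tsv", **_WRITE_KW)

    pd.DataFrame(
        [
            {
                "embryo_id": e.embryo_id,
                "segment_id": e.segment_id,
                "side": e.side,
                "t_min": e.t_event,
                "source": e.source,
                "delta_n": e.delta_n,
            }
            for e in ds.events
        ],
        columns=["embryo_id", "segment_id", "side", "t_min", "source", "delta_n"],
    ).to_csv(path / "events.tsv", **_WRITE_KW)

    pd.DataFrame(
        [
            {
                "embryo_id": r.embryo_id,
                "marker": r.marker,
                "stage": r.stage,
                "I": r.I,
                "I_DV": r.I_DV,
                "n_interfaces": r.n_interfaces,
            }
            for r in ds.intensities
        ],
        columns=["embryo_id", "marker", "stage", "I", "I_DV", "n_interfaces"],
    ).to_csv(path / "intensities.tsv", **_WRITE_KW)

    snap_rows = []
    for s in ds.snapshots:
        for i, cell in enumerate(s.cells):
            snap_rows.append(
                {
                    "embryo_id": s.embryo_id,
                    "segment_id": s.segment_id,
                    "compartment": s.compartment,
                    "stage": s.stage,
                    "distance_from_canthus_cells": s.distance_from_canthus_cells,
                    "is_central_most": s.is_central_most,
                    "cell_index": i,
                    "has_interlocked": cell.has_interlocked_interface,
                    "dv_um": cell.dv_length,
                    "ap_um": cell.ap_length,
                }
            )
    pd.DataFrame(
        snap_rows,
        columns=[
            "embryo_id", "segment_id", "compartment", "stage",
            "distance_from_canthus_cells", "is_central_most", "cell_index",
            "has_interlocked", "dv_um", "ap_um",
        ],
    ).to_csv(path / "snapshots.tsv", **_WRITE_KW)

    meta = {
        "embryo_id": ds.embryo_id,
        "genotype_label": ds.genotype_label,
        "timeline": {
            "t_E": ds.timeline.t_E,
            "t_completion": ds.timeline.t_completion,
            "frame_interval_length": ds.timeline.frame_interval_length,
            "frame_interval_count": ds.timeline.frame_interval_count,
            "t_F": [
                [seg, comp, t]
                for (seg, comp), t in sorted(ds.timeline.t_F_by_compartment.items())
            ],
        },
        "grids": {
            "flanks": [
                {"side": f.side, "t_L": f.t_L.tolist(), "t_N": f.t_N.tolist()}
                for f in ds.flanks
            ],
            "compartments": [
                {
                    "segment_id": c.segment_id,
                    "compartment": c.compartment,
                    "side": c.side,
                    "t_W": c.t_W.tolist(),
                    "t_n": c.t_n.tolist(),
                    "visible_from": None if np.isneginf(c.visible_from) else c.visible_from,
                }
                for c in ds.compartments
            ],
        },
        "provenance": ds.provenance,
    }
    with open(path / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _chord_angle_of(polyline) -> float:
    dx, dy = np.asarray(polyline[-1], float) - np.asarray(polyline[0], float)
    if dx == 0 and dy == 0:
        return math.nan
    return math.degrees(math.atan2(abs(dy), abs(dx)))


def read_dataset(path) -> EmbryoDataset:
    """Load and validate an embryo dataset written by :func:`write_dataset`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise ValidationError(f"{path} is not a dataset directory (no metadata.json)")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)

    timeline = TimelineConvention(
        t_E=meta["timeline"]["t_E"],
        t_completion=meta["timeline"]["t_completion"],
        frame_interval_length=meta["timeline"]["frame_interval_length"],
        frame_interval_count=meta["timeline"]["frame_interval_count"],
        t_F_by_compartment={(seg, comp): t for seg, comp, t in meta["timeline"]["t_F"]},
    )

    flank_tab = pd.read_csv(path / "flanks.tsv", **_READ_KW)
    rep_path = path / "flank_replicates.tsv"
    rep_tab = pd.read_csv(rep_path, **_READ_KW) if rep_path.exists() else None

    flanks = []
    for g in meta["grids"]["flanks"]:
        sub = flank_tab[flank_tab["side"] == g["side"]]
        t_L = np.array(g["t_L"], float)
        t_N = np.array(g["t_N"], float)
        L = _grid_values(t_L, sub["t_min"], sub["L_um"])
        N = _grid_values(t_N, sub["t_min"], sub["N_cells"])
        replicate_L = None
        if rep_tab is not None:
            rsub = rep_tab[rep_tab["side"] == g["side"]]
            if len(rsub):
                wide = rsub.pivot(index="t_min", columns="replicate", values="L_um")
                wide = wide.reindex(t_L)
                replicate_L = wide.to_numpy(float)
        flanks.append(FlankTrack(side=g["side"], t_L=t_L, L=L, t_N=t_N, N=N,
                                 replicate_L=replicate_L))

    comp_tab = pd.read_csv(path / "compartments.tsv", **_READ_KW)
    compartments = []
    for g in meta["grids"]["compartments"]:
        sub = comp_tab[
            (comp_tab["segment_id"] == g["segment_id"])
            & (comp_tab["compartment"] == g["compartment"])
            & (comp_tab["side"] == g["side"])
        ]
        t_W = np.array(g["t_W"], float)
        t_n = np.array(g["t_n"], float)
        compartments.append(
            CompartmentTrack(
                segment_id=g["segment_id"],
                compartment=g["compartment"],
                side=g["side"],
                t_W=t_W,
                W=_grid_values(t_W, sub["t_min"], sub["W_um"]),
                t_n=t_n,
                n=_grid_values(t_n, sub["t_min"], sub["n_cells"]),
                visible_from=-np.inf if g["visible_from"] is None else g["visible_from"],
            )
        )

    iface_tab = pd.read_csv(path / "interfaces.tsv", **_READ_KW)
    interfaces = []
    for _, row in iface_tab.iterrows():
        curved = row["curved_flag"]
        interfaces.append(
            InterfaceRecord(
                embryo_id=row["embryo_id"],
                segment_id=row["segment_id"],
                compartment=row["compartment"],
                t=float(row["t_min"]),
                polyline=np.array(json.loads(row["polyline"]), float),
                endpoint_vertex_degrees=(int(row["vdeg_a"]), int(row["vdeg_b"])),
                connects_two_DV=_as_bool(row["connects_two_DV"]),
                stage=row["stage"],
                curved_flag=None if pd.isna(curved) else _as_bool(curved),
            )
        )

    ev_tab = pd.read_csv(path / "events.tsv", **_READ_KW)
    events = [
        AdditionEvent(
            embryo_id=row["embryo_id"],
            segment_id=row["segment_id"],
            side=row["side"],
            t_event=float(row["t_min"]),
            source=row["source"],
            delta_n=int(row["delta_n"]),
        )
        for _, row in ev_tab.iterrows()
    ]

    int_tab = pd.read_csv(path / "intensities.tsv", **_READ_KW)
    intensities = [
        IntensityRecord(
            embryo_id=row["embryo_id"],
            marker=row["marker"],
            stage=row["stage"],
            I=float(row["I"]),
            I_DV=float(row["I_DV"]),
            n_interfaces=int(row["n_interfaces"]),
        )
        for _, row in int_tab.iterrows()
    ]

    snapshots = []
    snap_path = path / "snapshots.tsv"
    if snap_path.exists():
        snap_tab = pd.read_csv(snap_path, **_READ_KW)
        keys = ["embryo_id", "segment_id", "compartment", "stage",
                "distance_from_canthus_cells", "is_central_most"]
        if len(snap_tab):
            for vals, sub in snap_tab.groupby(keys, sort=False):
                sub = sub.sort_values("cell_index")
                cells = [
                    CellEntry(
                        has_interlocked_interface=_as_bool(r["has_interlocked"]),
                        dv_length=float(r["dv_um"]),
                        ap_length=float(r["ap_um"]),
                    )
                    for _, r in sub.iterrows()
                ]
                snapshots.append(
                    CompartmentSnapshot(
                        embryo_id=vals[0],
                        segment_id=vals[1],
                        compartment=vals[2],
                        stage=vals[3],
                        distance_from_canthus_cells=int(vals[4]),
                        is_central_most=_as_bool(vals[5]),
                        cells=cells,
                    )
                )

    ds = EmbryoDataset(
        embryo_id=meta["embryo_id"],
        genotype_label=meta["genotype_label"],
        timeline=timeline,
        flanks=flanks,
        compartments=compartments,
        interfaces=interfaces,
        events=events,
        intensities=intensities,
        snapshots=snapshots,
        provenance=meta.get("provenance", {}),
    )
    try:
        ds.validate()
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err
    return ds


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "1")


def to_retrospective(ds: EmbryoDataset) -> EmbryoDataset:
    """Re-express all time axes so completion of closure sits at t = 0.

    The shift is affine and order-preserving: every stored time is moved by
    ``-t_completion``.  A dataset already on the retrospective axis is
    returned unchanged (as a copy).  Raises if no completion time is known,
    in which case only prospective analyses are possible.
    """
    t_c = ds.timeline.t_completion
    if t_c is None or (isinstance(t_c, float) and math.isnan(t_c)):
        raise ValidationError(
            "no completion frame identified; use prospective-time analysis instead"
        )
    out = copy.deepcopy(ds)
    if t_c == 0:
        return out
    shift = -t_c
    out.timeline.t_E += shift
    out.timeline.t_completion = 0.0
    out.timeline.t_F_by_compartment = {
        k: v + shift for k, v in out.timeline.t_F_by_compartment.items()
    }
    for f in out.flanks:
        f.t_L = f.t_L + shift
        f.t_N = f.t_N + shift
    for c in out.compartments:
        c.t_W = c.t_W + shift
        c.t_n = c.t_n + shift
        if not np.isneginf(c.visible_from):
            c.visible_from += shift
    for rec in out.interfaces:
        rec.t += shift
    for ev in out.events:
        ev.t_event += shift
    return out
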