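"""Typing of cell-addition events and width changes around them.

Stripes gain leading-edge cells during closure through two routes: "mixer
cells" crossing the compartment boundary from the anterior, and "posterior
intercalating cells" joining from the row ventral to the leading edge.
Each addition episode is typed by what it does to the cell-number
disparity ΔDME = |n_upper − n_lower| between contralateral partner stripes:

* Type 1 — ΔDME = 0 throughout, no addition in either partner;
* Type 2 — ΔDME unchanged, additions in both partner stripes;
* Type 3 — ΔDME reduced, addition in the stripe with the lower count;
* other — every remaining combination (e.g. a disparity-increasing
  addition, or an addition on the higher-count side), which is observed
  but falls outside the three named types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fusefid.datamodel import AdditionEvent
from fusefid.metrics import norm_diff


@dataclass
class RearrangementLabel:
    label: str
    ddme_before: int
    ddme_after: int


def classify_rearrangement(
    ddme_before: int,
    ddme_after: int,
    added_upper: int,
    added_lower: int,
    lower_count_side: str,
) -> RearrangementLabel:
    """Type one addition episode from integer counts around its window.

    ``ddme_before``/``ddme_after`` are |n_u − n_l| at the last count-frame
    before, and the first count-frame after, the episode.  ``added_upper``/
    ``added_lower`` count cells added to each partner during the episode.
    ``lower_count_side`` names the partner with the lower count before the
    episode ("tie" when equal).  The rule table is exhaustive and mutually
    exclusive; anything outside the three named types is labelled "other".
    """
    for name, v in (("ddme_before", ddme_before), ("ddme_after", ddme_after),
                    ("added_upper", added_upper), ("added_lower", added_lower)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if lower_count_side not in ("upper", "lower", "tie"):
        raise ValueError(f"unknown lower_count_side {lower_count_side!r}")

    no_addition = added_upper == 0 and added_lower == 0
    if ddme_before == 0 and ddme_after == 0 and no_addition:
        label = "type1"
    elif ddme_before == ddme_after and added_upper > 0 and added_lower > 0:
        label = "type2"
    elif (
        ddme_after < ddme_before
        and lower_count_side != "tie"
        and (added_upper if lower_count_side == "upper" else added_lower) > 0
    ):
        label = "type3"
    else:
        label = "other"
    return RearrangementLabel(label=label, ddme_before=ddme_before, ddme_after=ddme_after)


@dataclass
class WidthChangeAtAddition:
    """Normalized width disparity around a cell-addition episode.

    Slots are NaN (and listed in ``missing``) when the episode sits too
    close to a track boundary for the corresponding frame to exist.
    """

    pre_cr: float
    at_cr: float
    post_cr: float
    missing: tuple = ()


def _width_at(track, t_query):
    """Width at the nearest sampled visible frame, NaN if none within half the window."""
    ok = ~np.isnan(track.W)
    if not ok.any():
        return np.nan
    t, w = track.t_W[ok], track.W[ok]
    i = int(np.argmin(np.abs(t - t_query)))
    if abs(t[i] - t_query) > 5.0 + 1e-9:  # no frame anywhere near the query time
        return np.nan
    return float(w[i])


def width_change_at_addition(upper_track, lower_track, event: AdditionEvent,
                             offset_min: float = 10.0) -> WidthChangeAtAddition:
    """Normalized width disparity ~10 min before, at, and ~10 min after an event.

    Widths of the contralateral partner stripes are read at the nearest
    sampled frames to ``t_event − offset``, ``t_event`` and
    ``t_event + offset`` and turned into normalized differences.  Events
    near a track boundary yield a partial result with the affected slots
    flagged.
    """
    times = {
        "pre_cr": event.t_event - offset_min,
        "at_cr": event.t_event,
        "post_cr": event.t_event + offset_min,
    }
    vals, missing = {}, []
    for slot, tq in times.items():
        wu, wl = _width_at(upper_track, tq), _width_at(lower_track, tq)
        if np.isnan(wu) or np.isnan(wl):
            vals[slot] = np.nan
            missing.append(slot)
        else:
            vals[slot] = norm_diff(wu, wl)
    return WidthChangeAtAddition(
        pre_cr=vals["pre_cr"], at_cr=vals["at_cr"], post_cr=vals["post_cr"],
        missing=tuple(missing),
    )
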