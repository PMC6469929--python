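"""Fidelity descriptors between the two fusing flanks.

The core descriptor is the normalized difference between a contralateral
pair of measurements,

    norm_diff(u, l) = (u - l) / ((u + l) / 2),

applied to whole-arc lengths (Norm.ΔArclength), fusing-front widths
(Norm.ΔWidth) and leading-edge cell counts (Norm.ΔDME).  It is signed
(upper minus lower), dimensionless and scale-free, and algebraically
bounded: |norm_diff| < 2 for positive inputs, reaching 2 only when one
count is zero.

Also here: the population-variance summary of ΔDME across partner pairs and
embryos, the constriction index (front width per leading-edge cell), the
D/V-referenced intensity normalization, and detection of the time at which
a disparity series equalizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from fusefid.datamodel import EmbryoDataset, IntensityRecord

DESCRIPTORS = ("arc_length", "width", "dme_arc", "dme_compartment")

#: Default equalization tolerance per descriptor: count series are
#: integer-valued so exact equality is required; length/width tracings are
#: noisy manual measurements and get a small band.
DEFAULT_EPSILON = {
    "arc_length": 0.05,
    "width": 0.05,
    "dme_arc": 0.0,
    "dme_compartment": 0.0,
}


def norm_diff(upper, lower):
    """Normalized difference (upper − lower) / mean of the pair.

    Accepts scalars or arrays (element-wise).  Inputs must be non-negative
    with a positive pair sum; NaN inputs propagate to NaN.
    """
    u = np.asarray(upper, dtype=float)
    l = np.asarray(lower, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(u < 0) or np.any(l < 0):
            raise ValueError("norm_diff requires non-negative measurements")
    s = u + l
    both_zero = (s == 0) & ~np.isnan(s)
    if np.any(both_zero):
        raise ValueError("norm_diff undefined when both measurements are zero")
    with np.errstate(invalid="ignore"):
        out = (u - l) / (s / 2.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class DisparitySeries:
    """A normalized-difference descriptor evaluated over time for one pair."""

    descriptor: str
    pair_id: str
    t: np.ndarray
    value: np.ndarray
    equalization_time: Optional[float] = None

    def detect_equalization(self, epsilon: Optional[float] = None, hold: int = 2):
        """Run :func:`equalization_time` and store the result on the series."""
        if epsilon is None:
            epsilon = DEFAULT_EPSILON[self.descriptor]
        self.equalization_time = equalization_time(self, epsilon=epsilon, hold=hold)
        return self.equalization_time


def _pair_series(t_u, v_u, t_l, v_l):
    """Align two (t, value) tracks on their common frames."""
    common, iu, il = np.intersect1d(t_u, t_l, return_indices=True)
    return common, v_u[iu], v_l[il]


def disparity_series(
    ds: EmbryoDataset,
    descriptor: str,
    pair_id="whole-arc",
    window=None,
) -> DisparitySeries:
    """Frame-wise normalized difference for one contralateral pair.

    Parameters
    ----------
    descriptor : {"arc_length", "dme_arc", "width", "dme_compartment"}
        Which measurement to compare.  The first two act on the whole-arc
        flank tracks; the others need ``pair_id = (segment_id, compartment)``.
    window : (t_lo, t_hi), optional
        Restrict the series.  Defaults: whole-arc cell counts to
        [t_F − 100, completion] (counts cannot be made earlier because the
        cells are not yet distinct in a dorsal-up view); arc length to the
        full traced track; compartments to [visible_from, t_F of the pair].

    Frames where either member is missing are skipped, not interpolated.
    """
    if descriptor not in DESCRIPTORS:
        raise KeyError(f"unknown descriptor {descriptor!r}")

    if descriptor in ("arc_length", "dme_arc"):
        up, lo = ds.flank("upper"), ds.flank("lower")
        if descriptor == "arc_length":
            t, vu, vl = _pair_series(up.t_L, up.L, lo.t_L, lo.L)
        else:
            t, vu, vl = _pair_series(up.t_N, up.N, lo.t_N, lo.N)
            if window is None:
                window = (-100.0, ds.timeline.t_completion)
        pid = "whole-arc"
    else:
        if not (isinstance(pair_id, tuple) and len(pair_id) == 2):
            raise KeyError(f"compartment descriptor needs (segment_id, compartment), got {pair_id!r}")
        seg, comp = pair_id
        try:
            cu = ds.compartment(seg, comp, "upper")
            cl = ds.compartment(seg, comp, "lower")
        except KeyError as err:
            raise KeyError(f"no compartment pair {pair_id!r} in dataset") from err
        if descriptor == "width":
            t, vu, vl = _pair_series(cu.t_W, cu.W, cl.t_W, cl.W)
        else:
            t, vu, vl = _pair_series(cu.t_n, cu.n, cl.t_n, cl.n)
        if window is None:
            t_f = ds.timeline.t_F_by_compartment.get((seg, comp), ds.timeline.t_completion)
            window = (max(cu.visible_from, cl.visible_from), t_f)
        pid = f"{seg}/{comp}"

    ok = ~(np.isnan(vu) | np.isnan(vl))
    if window is not None:
        ok &= (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    t, vu, vl = t[ok], vu[ok], vl[ok]
    if t.size == 0:
        raise ValueError(
            f"pair {pid} has no common visible frames for descriptor {descriptor!r}"
        )
    return DisparitySeries(descriptor=descriptor, pair_id=pid, t=t,
                           value=np.asarray(norm_diff(vu, vl)))


def equalization_time(series: DisparitySeries, epsilon: float, hold: int = 2):
    """Earliest time from which the disparity stays within ±epsilon.

    Returns the earliest time ``t*`` such that |value| ≤ epsilon at ``t*``
    and at every later frame, with at least ``hold`` consecutive frames of
    the series remaining from ``t*`` on.  Returns ``None`` when the series
    never settles (a valid outcome, not an error).
    """
    v = np.abs(series.value)
    above = np.nonzero(v > epsilon)[0]
    start = 0 if above.size == 0 else int(above[-1]) + 1
    if series.t.size - start < hold:
        return None
    return float(series.t[start])


@dataclass
class VarianceSummary:
    """ΔDME variance of partner pairs, per embryo and averaged over embryos."""

    relation: str
    per_embryo_sigma2: np.ndarray
    var_ddme: float
    n_embryos: int


def ddme_variance(pair_deltas_by_embryo, relation: str = "contralateral") -> VarianceSummary:
    """Population variance of ΔDME per embryo, then unweighted mean over embryos.

    Each embryo contributes the ΔDME of its partner pairs (typically 3
    contralateral or 4 ipsilateral pairs from segments A2–A4).  The
    per-embryo variance divides by the number of pairs N (population
    variance, not N−1); the cross-embryo summary is the plain arithmetic
    mean of the per-embryo variances.
    """
    if not pair_deltas_by_embryo:
        raise ValueError("ddme_variance requires at least one embryo")
    sig2 = []
    for embryo, deltas in pair_deltas_by_embryo.items():
        arr = np.asarray(list(deltas), dtype=float)
        if arr.size == 0:
            raise ValueError(f"embryo {embryo!r} contributes no pairs")
        sig2.append(float(np.var(arr)))  # ddof=0 by definition
    sig2 = np.array(sig2)
    return VarianceSummary(
        relation=relation,
        per_embryo_sigma2=sig2,
        var_ddme=float(np.mean(sig2)),
        n_embryos=sig2.size,
    )


def constriction_index(W: float, N: float) -> float:
    """Fusing-front width per leading-edge cell (µm/cell), W / N at fusion."""
    if N < 1:
        raise ValueError("constriction index needs at least one cell")
    if W <= 0:
        raise ValueError("constriction index needs a positive front width")
    return float(W) / float(N)


def normalized_intensity(rec: IntensityRecord) -> float:
    """Junctional intensity normalized to the D/V-interface reference, I / I_DV."""
    if rec.I_DV <= 0:
        raise ValueError("reference intensity I_DV must be positive")
    if rec.I < 0:
        raise ValueError("intensity I must be non-negative")
    return rec.I / rec.I_DV
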