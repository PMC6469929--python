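"""Group statistics and end-to-end pipeline orchestration.

Comparisons between genotype groups use the Mann–Whitney U (Wilcoxon
rank-sum) test for central tendency — exact for small untied samples,
tie-corrected normal approximation otherwise — and a two-sided
variance-ratio F test for dispersion.  Summaries are reported as
median ± interquartile range by default, or mean ± sd on request.

:func:`run_pipeline` executes the full analysis on a dataset collection
(simulated on the fly or loaded from disk): disparity descriptors and
equalization detection, interface classification, rearrangement typing,
and the group comparisons, emitting long-format TSV tables and one
machine-readable JSON report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from fusefid import geometry, metrics, rearrangement
from fusefid.io import write_dataset
from fusefid.simulate import SimulationConfig, simulate


@dataclass
class ComparisonResult:
    groups: tuple
    statistic_kind: str
    statistic: float
    p_value: float
    summary: dict
    n: tuple


def _summary(x, style: str) -> dict:
    x = np.asarray(x, float)
    if style == "median_iqr":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3))}
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0}


def compare_groups(a, b, kind: str = "rank_sum", summary_style: str = "median_iqr",
                   labels: tuple = ("a", "b")) -> ComparisonResult:
    """Two-sided comparison of two samples.

    ``kind="rank_sum"`` tests central tendency with the Mann–Whitney U
    statistic (exact enumeration when both samples are small and untied);
    ``kind="variance_ratio"`` tests dispersion with the F ratio of the two
    sample variances.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if kind == "rank_sum":
        if min(a.size, b.size) < 3:
            raise ValueError("rank_sum needs at least 3 observations per group")
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif kind == "variance_ratio":
        if min(a.size, b.size) < 2:
            raise ValueError("variance_ratio needs at least 2 observations per group")
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if vb == 0 and va == 0:
            stat, p = 1.0, 1.0
        else:
            stat = float(va / vb) if vb > 0 else float("inf")
            dist = stats.f(a.size - 1, b.size - 1)
            p = float(min(1.0, 2.0 * min(dist.cdf(stat), dist.sf(stat))))
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    return ComparisonResult(
        groups=tuple(labels),
        statistic_kind=kind,
        statistic=stat,
        p_value=min(p, 1.0),
        summary={labels[0]: _summary(a, summary_style), labels[1]: _summary(b, summary_style)},
        n=(int(a.size), int(b.size)),
    )


# ---------------------------------------------------------------------------
# pipeline


def analyze_embryo(ds) -> dict:
    """All per-embryo measurements the report aggregates."""
    out = {"embryo_id": ds.embryo_id, "genotype": ds.genotype_label}

    series = metrics.disparity_series(ds, "arc_length")
    series.detect_equalization()
    k = min(10, series.t.size)
    out["arc_disp_early"] = float(np.mean(np.abs(series.value[:k])))
    out["arc_disp_late"] = float(np.mean(np.abs(series.value[-k:])))
    out["t_eq_arc_length"] = series.equalization_time

    counts = metrics.disparity_series(ds, "dme_arc")
    counts.detect_equalization()
    out["t_eq_dme_arc"] = counts.equalization_time

    labels = [geometry.classify_interface(rec) for rec in ds.interfaces]
    eligible = [(rec, lab) for rec, lab in zip(ds.interfaces, labels)
                if lab.label != "ineligible"]
    out["n_interfaces"] = len(eligible)
    if eligible:
        out["mean_angle"] = float(np.mean([geometry.chord_angle(r.polyline)
                                           for r, _ in eligible]))
        out["frac_curved"] = float(np.mean([lab.label == "curved" for _, lab in eligible]))
        out["frac_interlocked"] = float(np.mean([
            geometry.interlocked(r.endpoint_vertex_degrees, lab) for r, lab in eligible
        ]))
    defect_states = [geometry.interlocking_defective(s) for s in ds.snapshots]
    assessed = [d for d in defect_states if d is not None]
    out["frac_defective"] = float(np.mean(assessed)) if assessed else float("nan")
    return out


def classify_events(ds) -> list:
    """Type every addition event of one embryo from its count tracks."""
    results = []
    for ev in ds.events:
        if ev.segment_id not in {c.segment_id for c in ds.compartments}:
            continue
        cu = ds.compartment(ev.segment_id, "stripe", "upper")
        cl = ds.compartment(ev.segment_id, "stripe", "lower")
        # last count frame strictly before the event, first at/after it
        before_idx = np.nonzero(cu.t_n < ev.t_event - 1e-9)[0]
        after_idx = np.nonzero(cu.t_n >= ev.t_event - 1e-9)[0]
        if before_idx.size == 0 or after_idx.size == 0:
            continue
        i0, i1 = before_idx[-1], after_idx[0]
        nu0, nl0 = cu.n[i0], cl.n[i0]
        nu1, nl1 = cu.n[i1], cl.n[i1]
        if np.isnan([nu0, nl0, nu1, nl1]).any():
            continue
        lower_side = "tie" if nu0 == nl0 else ("upper" if nu0 < nl0 else "lower")
        added_u, added_l = int(round(nu1 - nu0)), int(round(nl1 - nl0))
        lab = rearrangement.classify_rearrangement(
            int(round(abs(nu0 - nl0))), int(round(abs(nu1 - nl1))),
            max(added_u, 0), max(added_l, 0), lower_side,
        )
        results.append({
            "embryo_id": ds.embryo_id, "segment_id": ev.segment_id,
            "t_min": ev.t_event, "source": ev.source,
            "label": lab.label, "ddme_before": lab.ddme_before,
            "ddme_after": lab.ddme_after,
        })
    return results


def run_pipeline(config=None, datasets=None, out_dir=None, alpha: float = 0.01,
                 write_datasets: bool = False) -> dict:
    """Execute simulate → metrics → classify → rearrange → compare.

    Provide either a :class:`SimulationConfig` (datasets are generated) or
    an explicit list of datasets grouped by their ``genotype_label``.  The
    report compares the early vs late arc-length disparity within each
    genotype group (rank-sum) and flags a significant reduction at
    ``alpha``.  When ``out_dir`` is given, long-format TSV tables and a
    deterministic ``report.json`` are written there.
    """
    if datasets is None:
        if config is None:
            raise ValueError("run_pipeline needs a config or a list of datasets")
        datasets, _ = simulate(config)
    if not datasets:
        raise ValueError("empty dataset collection: nothing to analyze")

    rows = [analyze_embryo(ds) for ds in datasets]
    per_embryo = pd.DataFrame(rows)
    events = [r for ds in datasets for r in classify_events(ds)]
    event_tab = pd.DataFrame(events, columns=["embryo_id", "segment_id", "t_min",
                                              "source", "label", "ddme_before",
                                              "ddme_after"])

    report = {"n_embryos": len(datasets), "groups": {}, "comparisons": {}}
    for genotype, grp in per_embryo.groupby("genotype", sort=True):
        if len(grp) >= 3:
            cmp_res = compare_groups(grp["arc_disp_early"], grp["arc_disp_late"],
                                     kind="rank_sum", labels=("early", "late"))
            p_red, sig = cmp_res.p_value, bool(cmp_res.p_value < alpha)
        else:  # too few embryos for a rank-sum comparison
            p_red, sig = None, False
        entry = {
            "n": int(len(grp)),
            "arc_disparity_early_median": float(grp["arc_disp_early"].median()),
            "arc_disparity_late_median": float(grp["arc_disp_late"].median()),
            "disparity_reduction_p": p_red,
            "disparity_reduction_significant": sig,
            "median_t_eq_arc_length": _nanmedian(grp["t_eq_arc_length"]),
            "median_t_eq_dme_arc": _nanmedian(grp["t_eq_dme_arc"]),
            "mean_interface_angle": float(grp["mean_angle"].mean())
            if "mean_angle" in grp else None,
            "mean_frac_interlocked": float(grp["frac_interlocked"].mean())
            if "frac_interlocked" in grp else None,
            "mean_frac_defective": float(grp["frac_defective"].mean()),
            "event_type_counts": event_tab[
                event_tab["embryo_id"].isin(grp["embryo_id"])
            ]["label"].value_counts().to_dict(),
        }
        report["groups"][genotype] = entry

    genotypes = sorted(report["groups"])
    if len(genotypes) == 2:
        g0, g1 = genotypes
        a = per_embryo.loc[per_embryo["genotype"] == g0, "mean_angle"].dropna()
        b = per_embryo.loc[per_embryo["genotype"] == g1, "mean_angle"].dropna()
        if len(a) >= 3 and len(b) >= 3:
            res = compare_groups(a, b, labels=(g0, g1))
            report["comparisons"]["mean_interface_angle"] = {
                "groups": [g0, g1], "p_value": res.p_value,
                "significant": bool(res.p_value < alpha),
            }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_embryo.to_csv(out_dir / "per_embryo.tsv", sep="\t", index=False, na_rep="NA")
        event_tab.to_csv(out_dir / "rearrangements.tsv", sep="\t", index=False, na_rep="NA")
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if write_datasets:
            for ds in datasets:
                write_dataset(ds, out_dir / "datasets" / ds.embryo_id)
    return report


def _nanmedian(col) -> float:
    vals = pd.to_numeric(col, errors="coerce").dropna()
    return float(vals.median()) if len(vals) else float("nan")
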