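"""Disparity descriptors on one simulated control embryo.

Generates a single tracked embryo, computes the normalized arc-length and
DME cell-number differences between the two fusing flanks, and detects
when each descriptor equalizes.  Disparity values are dimensionless
(difference over pair mean, bounded by ±2); times are retrospective
minutes with 0 = completion of closure.
"""

import numpy as np

from fusefid import SimulationConfig, disparity_series, simulate

(ds,), truth = simulate(SimulationConfig(seed=42, n_embryos=1))

arc = disparity_series(ds, "arc_length")
arc.detect_equalization()
count = disparity_series(ds, "dme_arc")
count.detect_equalization()

print(f"embryo {ds.embryo_id} ({ds.genotype_label})")
print(f"|Norm.dArclength| at -190 min : {abs(arc.value[0]):.3f}")
print(f"|Norm.dArclength| at -100 min : {abs(arc.value[np.argmin(np.abs(arc.t + 100))]):.3f}")
print(f"arc length equalizes at       : {arc.equalization_time:.0f} min")
print(f"DME cell count equalizes at   : {count.equalization_time:.0f} min")
print(f"(generator truth: {truth.equalization[ds.embryo_id]})")
print()
print("The flanks start unequal and become symmetric well before closure;")
print("length equalizes before cell number, mirroring the fusion chronology.")
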