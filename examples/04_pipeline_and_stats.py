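"""End-to-end pipeline: control vs tension-deficient cohorts.

Runs the full analysis (descriptors, equalization detection, interface
classification, event typing, group statistics) on 16 simulated embryos
per condition and prints the headline numbers of the report.
"""

from fusefid import SimulationConfig, run_pipeline

for mode in ("control", "tension_deficient"):
    rep = run_pipeline(config=SimulationConfig(seed=1, n_embryos=16, mode=mode))
    g = rep["groups"][mode]
    print(f"{mode}:")
    print(f"  |Norm.dArclength| median early {g['arc_disparity_early_median']:.3f} "
          f"-> late {g['arc_disparity_late_median']:.3f}")
    print(f"  disparity reduction rank-sum p = {g['disparity_reduction_p']:.2e} "
          f"(significant: {g['disparity_reduction_significant']})")
    print(f"  median equalization: length {g['median_t_eq_arc_length']} min, "
          f"count {g['median_t_eq_dme_arc']} min")
    print(f"  interlocking-defective fraction = {g['mean_frac_defective']:.2f}")
    print()
print("Control flanks equalize (tiny p, defect-free seam); tension-deficient")
print("flanks stay as unequal as they started and fail to interlock.")
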