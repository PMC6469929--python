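# Methods

## Measurement model and conventions

The unit of analysis is one embryo's set of tracked tables: two whole-arc
flank tracks (arc length *L*, DME cell count *N*), per-compartment tracks
(fusing-front width *W*, compartment DME count *n*) for both sides of each
tracked segment, interface records (2-D polylines in µm, endpoint vertex
degrees, stage), cell-addition events, per-cell interlocking snapshots and
D/V-referenced intensity records.

Units are µm and minutes throughout; angles in degrees. Time is
retrospective (0 = completion of closure, negative before). Two sampling
grids coexist, reflecting how such measurements are made: lengths and
widths at every movie frame (1 min), cell counts at 5-min intervals.
Descriptors that combine both grids are evaluated on the 5-min grid.
Missing measurements — peripheral compartments before they become visible
in a dorsal-up view — are NaN and are *skipped*, never interpolated. The
coordinate convention is x anterior→posterior, y across the midline;
every reported angle is the acute angle to x, in [0°, 90°].

## Disparity descriptors

`norm_diff(u, l) = (u − l) / ((u + l)/2)` is signed (upper minus lower),
scale-free, antisymmetric, zero iff the pair is equal, and |·| < 2 for
positive inputs (= 2 exactly when one count is 0). Whole-arc cell-count
series start at −100 min by default (counts cannot be made earlier: the
cells are not yet distinct), whereas arc-length series span the full
traced track from −190 min; compartment series run from joint visibility
to the pair's fusion time. Replicate tracings are averaged arithmetically
and fractional mean counts feed `norm_diff` unrounded; the integer ΔDME
used for variance summaries and event typing comes from the exact counts.

The ΔDME variance divides by the number of pairs N (population variance,
as defined, not N−1) within each embryo and averages the per-embryo
variances without weighting.

**Equalization time** has no printed operational definition in the field,
so one is fixed here: the earliest time t\* from which |value| ≤ ε through
the end of the series, with at least `hold = 2` frames remaining. Defaults
are ε = 0 for integer count series and ε = 0.05 for length/width tracings
(manual tracing noise); both are arguments. This "no re-divergence" rule
is the strict reading; relaxing it is possible by raising ε or shrinking
`hold`.

## Interface geometry

Angles are measured on the endpoint chord of the polyline for all classes,
including curved interfaces. The printed class bins share the 20°
boundary; the partition is made well-defined by closing the angular bin
from below (angular = [20°, 90°], straight = [0°, 20°)), exposed as
`angle_split`. "Curved/squiggly" is identified by eye in practice; here it
is operationalized as sinuosity (polyline length / chord length) above a
configurable threshold, default 1.05, with an optional manual
`curved_flag` that overrides the rule. "Interlocked" is likewise
operationalized: classified angular *and* both endpoint vertices
tricellular (degree 3). The 70% interlocking-defect rule, the Lb/A7
exclusion, the 10-cells-from-canthus rule during closure and the
central-most exclusion post closure are applied verbatim; non-assessable
compartments return `None`, never a boolean.

## Rearrangement typing

ΔDME is the absolute count difference at the last count frame before and
the first at/after the addition window. "Type 3" is read as: ΔDME reduced
*and* an addition occurred on the lower-count side; a simultaneous gain on
the higher side does not disqualify (such a case can never be Type 2,
whose definition requires ΔDME unchanged). Combinations outside the three
named types — disparity-increasing additions, additions on the higher
side only — are labelled `other`. Width changes around an addition are
read at the nearest sampled frames to t−10, t, t+10 min; slots beyond the
track boundary are flagged missing rather than extrapolated.

## Statistics

Central-tendency comparisons use the Mann–Whitney U test (the test the
phrase "Mann-Whitney unpaired t-test" denotes): exact enumeration when
both groups are ≤ 20 and untied, tie-corrected normal approximation with
continuity correction otherwise (delegated to `scipy.stats.mannwhitneyu`).
Dispersion comparisons use a two-sided variance-ratio F test
(F = s₁²/s₂², p = 2·min(P(F ≤ f), P(F ≥ f))). No multiple-testing
correction is applied; comparisons are reported per test. Null
calibration is checked at 50 observations per group, where the attainable
significance levels of the (discrete) rank statistic are dense enough
that the rejection rate is indistinguishable from the nominal α; at very
small group sizes any exact rank test is necessarily conservative.

## Synthetic-data generator

The generator is phenomenological at the measurement level (no vertex or
force model). Its defaults encode the study conditions:

* **Chronology**: first analyzable frame −190 min; peripheral segments
  Lb/A7 fuse at −130; zippering onset −100; central segments in
  succession, A3 last at 0. Tension-deficient mode delays fusion by
  20 min.
* **Arc dynamics**: mean arc length 350 → 40 µm, linear in time. The
  arc-length disparity starts at 10–20% (random sign) and ramps to zero
  over the 15 min before −100 min; the whole-arc count disparity (2–4
  cells on a base of ~60) is eliminated by discrete single-cell additions
  on the low side, the last landing exactly at −50 min. Disparity decay is
  realized by scheduled discrete additions, not a continuous relaxation,
  matching the discrete cell-count mechanism. In the tension-deficient
  mode both disparities are constant in time.
* **Ground-truth equalization times** are obtained by applying the
  detector definition to the noise-free disparity trajectory, so truth and
  estimate share a single operational definition.
* **Compartments**: stripe DME counts 4–6, interstripes 9–12 (stripes
  carry about half the cells of interstripes); initial pair disparity
  ΔDME ∈ {0,1,2} with probabilities (0.25, 0.50, 0.25); the
  disparity at fusion is drawn per mode — control (0.538, 0.462, 0)
  (46.2% one-cell disparities, none of two), baz-deficient shifts 16.6%
  of mass to ΔDME = 2, and interstripes and the tension-deficient mode
  keep their initial disparity. The path from initial to fusion disparity
  is realized as Type 3 steps, optionally interleaved with one Type 2
  (probability 0.4) and one disparity-increasing `other` step
  (probability 0.15), spaced ≥ 2 count frames apart.
* **Widths**: stripe fronts 15 → 12 µm, interstripes 30 → 25 µm, with a
  10–25% pair disparity relaxing with τ = 40 min; each Type 3 addition
  transiently collapses the width disparity (×0.15 within ±3 min) and
  halves it thereafter ("transient or sustained equalization").
* **Interface kinetics**: en-face contacts interlock after a truncated
  normal delay, mean 15.9 min (control) or 24.6 min (baz-deficient); the
  sd of 7.7 min is reconstructed from the reported sem·√n. Interlocked
  interfaces get tricellular endpoints and chord angles drawn from a
  truncated normal (mean 39.7° control, 32.3° baz-deficient, sd 5°,
  support [20°, 90°]); baz-deficient interfaces are curved (target
  sinuosity 1.15 via midpoint displacement of a 3-point polyline) with
  probability 0.6; tension-deficient interfaces never remodel. Bazooka
  recruitment delay (11.2 min) and actin clearance (10.9 min control,
  ≥ 20 min baz-deficient) are carried in the intensity kinetics and
  ground truth.
* **Snapshots**: 10 cells per compartment with exactly 1 (control), 9
  (tension-deficient) or 8 (baz-deficient) cells lacking interlocked
  interfaces, so defect calls are deterministic; high-aspect-ratio cells
  (D/V:A/P ≥ 6) appear only in the perturbation modes.
* **Noise**: multiplicative Gaussian with CV 2% per tracing on lengths
  and widths, averaged over 6 replicate tracings (effective sd ≈ 0.8%);
  counts are exact integers — the replicate-averaging convention applies
  to tracings, and noise-free counts keep the ε = 0 equalization
  definition for integer series meaningful. Reported kinetic means are
  given without distributions; truncated normals are used and the choice
  is exposed in the config.

What the generator does **not** emulate: segmentation/tracking errors,
drift or registration artifacts, embryo-to-embryo variation in absolute
geometry beyond the sampled ranges, correlated noise along a tracing, or
any mechanical coupling between neighboring compartments. Passing
recovery tests on this synthetic data therefore validates the *analysis
logic* (descriptor algebra, detector definitions, classifier rules, and
their inversion of the generative schedule), not robustness to real
imaging pathologies.

## Problem sizes and determinism

The shipped tests and the acceptance script run cohorts of 16 embryos
(50 single-embryo runs for equalization recovery, 100 embryos for
rearrangement recovery, 20 replicates for mode separation, 10⁴ null
simulations for calibration) — sizes at which every recovered quantity is
stable yet the full suite completes in seconds. All randomness flows from
a single `numpy.random.default_rng(seed)`; identical seed + config yield
byte-identical serialized datasets and reports (floats are written with
`%.17g` and parsed round-trip).

## Known limitations

* The seam-straightness phenotype is qualitative in origin and excluded.
* Curved-interface angles use the endpoint chord; a fitted line could
  differ for strongly sinuous interfaces.
* Bilateral snapshots are not supported; interlocking is scored per side.
* The intensity module normalizes per averaging set; per-embryo pooling
  before normalization would weight embryos differently.
* Whole-arc cell additions are bookkept in the ground truth rather than
  as stripe-level events, since the whole-arc count is a separate
  measurement from the compartment counts (fused segments leave the
  between-canthi count as zippering proceeds).
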