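# Methods

This note records the models, parameter choices and numerical decisions
behind `autoplan`, and what the synthetic setting does and does not show.

## Phantoms

The phantom generator produces the geometric situation of pancreatic SBRT
planning rather than any particular patient: a water-equivalent body
outline, a ~30 mm spherical/circular PTV, a serial OAR ("duodenum", a 9–10 mm
radius tube) abutting the target at a surface gap of at most 5 mm, a distant
serial OAR ("cord") at least 60 mm posterior, and two lateral parallel OARs
("kidney_l"/"kidney_r", ellipsoids). Two presets exist: `pancreas2d`
(96×96×1 voxels at 4 mm — the fast fixture used throughout the tests) and
`pancreas3d` (64×64×32 at 4 mm). The seed drives a ±1 mm jitter of structure
centers, emulating per-patient variation while keeping the abutment and
stand-off constraints; identical (preset, seed) pairs are bit-identical.

Ring structures are built from the Euclidean distance transform of the
target complement (sampled at voxel centers with the grid spacing), which
for voxels outside the target equals the distance to the nearest
target-surface voxel center; this is verified against a brute-force
all-pairs distance computation in the tests. Rings exclude targets and
previously built rings but may overlap OARs, mirroring common
treatment-planning practice; empty rings (offsets beyond the body) are
dropped with a warning.

## Dose model

The dose engine is deliberately simple and linear: arcs are approximated by
36 equispaced coplanar static beams (a standard research surrogate for
VMAT), each a fan of parallel 4 mm beamlets covering the target plus a
10 mm margin. A beamlet deposits
`C · exp(−μ·depth) · exp(−r²/(2σ_p²))` with μ = 0.005 /mm (an effective
6 MV attenuation in water), σ_p = 0.6 × beamlet width, depth the
water-equivalent path length found by 2 mm ray marching through the body
mask, and C calibrated so a unit-fluence beamlet gives 1 Gy at 100 mm depth
on axis. Entries below 1e-4 of a beamlet's maximum are truncated (the
induced voxel-dose error is below 0.5%, checked against the untruncated
operator). The body is homogeneous water; there is no buildup, scatter
kernel or heterogeneity correction. The controller is dose-model-agnostic,
so this surrogate suffices to exercise it; absolute dose values should not
be read as clinical.

All doses are total plan dose; the five-fraction prescription is metadata.

## Objectives

All objectives share the relative-quadratic, volume-normalized form given
in the README. Design choices: the overdose penalty sums over *all* voxels
above the objective dose (the fractional volume attached to a DVH-point
objective only records which DVH point seeded it); `dv_i` is normalized by
the structure's own volume so small and large structures contribute
comparably; the ring mean-dose objective is one-sided (rings only need an
upper pull); min/uniform variants mirror the same relative-quadratic shape.
Gradients are analytic and verified against central finite differences to
1e-6 relative (away from the kink at `d_i = d_j`, where the penalty is C¹
but not C²).

`solve_objective_dose` inverts `F(d_j)` by bisection on
(0.01 Gy, max structure dose], exploiting strict monotonicity of F in the
objective dose wherever F > 0; tolerance 1e-6 relative in F, at most 200
bisections. A target value unreachable even at the 0.01 Gy floor flags the
objective as floored; an unirradiated structure gets a sentinel and is left
alone.

## Fluence optimizer

Projected gradient descent with Armijo backtracking and a safeguarded
Barzilai–Borwein step seed, on the non-negativity bound. Accepted objective
values are monotone non-increasing; iteration stops at 100 iterations or
when the composite objective changes by less than 1e-4 between accepted
iterates. The change is measured relative to the current objective value by
default (`tolerance_mode="relative"`); an absolute reading is available in
the settings. The DVH objective family is non-convex in general, so local
minima are accepted, as they are in commercial systems; on all-uniform
(convex) instances the solver matches L-BFGS-B to 0.1% in objective value
(cross-checked in the tests). The optimizer is fully deterministic — seeds
affect only phantom generation.

## Controller

Defaults: prescription 35 Gy to 95% of the PTV; rings 10 mm wide at
5/35/55 mm; weights 100 (target), 80 (rings), 1 (OARs); target objective
doses at 1.00/1.07/1.02 × prescription (min/max/uniform); ring max-dose
objectives at 0.95/0.70/0.45 and mean-dose at 0.60/0.35/0.15 × prescription
(our choice, enforcing a monotone fall-off; exposed in the config); five
DVH points per OAR equispaced on [1%, 70%]; OAR scaling factor 1.05;
termination at σ(PTV) = 5% of prescription; a safety cap of 20 outer
cycles.

Decisions taken where the design was genuinely open:

- **Scaling step.** The OAR objective dose is re-solved against the
  *current* dose distribution each cycle (not decremented on a fixed
  schedule), then clamped so it never increases across cycles even when the
  new root would be higher.
- **Stopping sense.** Cycles move σ upward from ~1%; the loop stops at the
  first cycle whose σ reaches the limit and returns the previous
  (last feasible) plan, so the delivered plan always satisfies σ ≤ 5%.
- **Normalization.** After every inner optimization the plan is rescaled so
  D95(PTV) equals the prescription exactly (exact because the dose model is
  linear; D95 here is the exact sort-based quantile). This keeps coverage
  identical across cycles and makes dose indices comparable.
- **σ convention.** Population (1/n) standard deviation, divided by the
  prescription dose; one shared implementation serves the termination check
  and the reported metrics.
- **Priorities.** Per-OAR priority multipliers scale the objective-value
  target of the adjustment step: a priority of 2 pins that organ's
  objectives at 2 × 1.05 × the target reference, pushing its objective
  doses lower and sparing it harder. The plain defaults leave all
  priorities at 1; the packaged reference configuration
  (`AutoPlanConfig.reference()`) doubles the duodenum priority.

### Observed dynamics

On the 2D reference phantom the initial (target + rings) plan reaches
σ ≈ 0.5–1.1% of prescription, and the loop needs five to seven
DVH-reduction cycles to drive σ to the 5% limit — each cycle multiplies σ
by roughly 1.3–1.6. A clinical optimizer on real 3D anatomy starts from a
σ nearer 2% and moves in larger per-cycle steps, reaching the same limit in
two to three cycles; the difference is a property of the simplified dose
model and easy 2D geometry, not of the controller logic. The qualitative
behavior — monotone OAR-dose ratcheting, monotone σ growth, strong sparing
of the abutting serial organ, and distance-dependent sparing of remote
organs — is reproduced and asserted in the test suite.

## Plan metrics

Cumulative DVHs use exact voxel counting on uniform 0.05 Gy bins. `D_v`
from a curve is the largest dose whose cumulative volume is still ≥ v,
interpolated linearly toward the next bin; it agrees with the sort-based
quantile (the coolest voxel among the hottest v% of voxels) to within one
bin width. Reported plan metrics (D95/D5/D2/Dmean/Dmax) use the exact
quantiles so that ordering invariants hold even for structures of a few
voxels. `D_v%` indices are fractional-volume; absolute-volume indices
(e.g. D_2cc) are supported with half-up voxel rounding. Paired plan
comparison reports auto/reference ratios (ratio < 1 ⇔ less dose in the
auto plan) and a related-samples Wilcoxon signed-rank test using the exact
null distribution for n ≤ 20 pairs (verified against exhaustive sign
enumeration).

## Problem sizes and limitations

Tests and the acceptance script run the full pipeline on the single-slice
2D preset (≈2800 body voxels, 468 beamlets), where a complete planning run
takes seconds; the 3D preset exists for realism but is not used in the
end-to-end runs. What passing tests show: the controller's contracts
(coverage conservation, monotone ratcheting, termination, the 5% objective
round-trip) and the numeric kernels' correctness against independent
oracles. What they do not show: agreement with a clinical dose engine,
deliverability (no MLC sequencing or arc modelling), or cohort-level
dosimetric gains on patient anatomies.
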