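# Methods

## Model and procedure

Pothole analysis treats white-matter integrity as an individual-deviation
problem rather than a group-contrast problem. Given a control cohort of
co-registered FA volumes with white-matter masks, the normative template
holds, per voxel, the control sample mean μ_v and sample SD σ_v (denominator
n−1), defined on the intersection of all control masks. A subject's deviation
map is z_v = (FA_v − μ_v)/σ_v on the template-valid voxels intersected with
the subject's own white-matter mask. Potholes are the connected components of
{v : z_v < −3} (strict inequality; a voxel at exactly −3 is excluded) that
reach a minimum extent, and the per-subject pothole count is the burden
measure used in group comparisons.

Assumptions: volumes are already registered to one grid (compatibility =
equal shape, voxel size within 1e-6 mm, and spatial-frame tag); FA noise is
exchangeable across control subjects at each voxel; the control cohort is
large enough that μ, σ estimates are usable (n ≥ 2 enforced, n ≈ 20
intended). No spatial smoothness is assumed or imposed by the pipeline
itself.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| z threshold | −3 | SD | the field's convention for "abnormally low" FA |
| min cluster size | 10 | voxels | a 10 mm³ filter is sub-voxel at DTI voxel volumes (~12.24 mm³ at 2×2.04×3 mm), hence inert; the voxel-count reading is the operative one. Both units supported (`size_units`). |
| connectivity | 26 | — | common default of 3D cluster tools; 6 and 18 available since conventions differ |
| sd_floor | 1e-6 | FA | excludes exactly-constant voxels from the valid mask so z-maps stay finite |
| control scoring | leave-one-out | — | a control included in its own reference has its z deflated by 1/n and its SD inflated; LOO removes that self-bias. Full-template mode (`loo_controls=False`) is available for strict one-template replication. Injured subjects always score against the full control template. |

Cluster ordering (size descending, ties by ascending lexicographic peak
index) and id assignment are fixed so outputs are reproducible; the peak is
the voxel attaining the cluster's minimum z.

## Statistical engine

All tests follow the classical textbook forms: one-way fixed-effects ANOVA
(F = MSB/MSW, df k−1 and N−k) with classical η² = SSB/SST; pooled-variance
t (df n₁+n₂−2) with Cohen's d = Δmean / pooled SD; Pearson χ² without
continuity correction; Mann-Whitney U from average ranks with tie-corrected
normal p; Spearman ρ as Pearson on average ranks with the t-approximate p on
n−2 df; Bonferroni adjustment min(1, p·m). The summary-statistics entry
points rebuild SSB from n·(mean − grand mean)² and SSW from (n−1)·sd², which
reproduces the raw-data ANOVA exactly for any data with those moments;
recomputing a published table's statistics this way is limited to roughly
0.5% relative agreement by the rounding of the printed means and SDs. The
pooled (not Welch) t and classical (not partial) η² were chosen because they
exactly reproduce the reference cohort's reported t(67) and η² values from
its printed summaries. Degenerate inputs are defined rather than crashed:
SST at rounding-noise level → F = 0, p = 1, η² = 0; zero within-group
variance with distinct means → F = ∞, p = 0; zero pooled variance with a
nonzero mean difference is an error. p-value distributions come from scipy;
the decompositions, reconstructions and rank statistics are implemented
here, and scipy's own test functions appear only as independent
cross-checks in the test suite.

Region-wise testing drops missing regions listwise and sizes the Bonferroni
family by the number of regions actually tested, not the atlas's nominal
count. TIV scaling is proportional (value × cohort-mean-TIV / TIV), the
simplest reading of "scaled by"; residual-regression normalization is out of
scope.

## Synthetic cohorts: what they emulate and what they don't

The generator reproduces the *design* of a three-group chronic-TBI study
(21 controls / 52 mild / 17 moderate-severe): a shared ellipsoidal
white-matter mask on a 32³ grid at 2×2.04×3 mm (desk-scale but large enough
for multi-lesion placement), a toy 8-region octant atlas with region-wise
constant mean FA spread over [0.35, 0.60], voxel-wise i.i.d. Gaussian noise
with SD 0.05 (a realistic between-subject FA SD in registered white matter;
the distributional form is this module's modeling choice, not an empirical
claim), and injured subjects built as fresh control draws with planted
contiguous hypo-FA lesions. Lesion FA is set to μ_v − depth·σ relative to
the *true* generating parameters, not the estimated template, so recovery
error isolates the pipeline's estimation noise; lesions are grown 6-connected
(or as cuboids), sized 20–40 voxels by default, separated by at least one
background voxel in the 26-neighborhood so each planted lesion is a distinct
component, and recorded voxel-by-voxel as ground truth. Per-subject lesion
counts in the demo pipeline are Poisson (means 3 and 4 for the mild and
moderate-severe groups) because fixed counts would give zero within-group
count variance — unlike the heavily over-dispersed counts real cohorts show —
and would break the pooled-t post hoc. Metadata tables draw each measure
Normal(mean, SD) truncated by clipping (age ≥ 18, scores ≥ 0, lifetime
injuries ≥ 1, negligible at the stated parameters) with the reference
cohort's printed group moments, and cause-of-injury categories with its
observed proportions.

Not emulated: Rician/spatially correlated MRI noise, partial-volume effects,
registration error, anatomically shaped tracts, or any correlation between
lesion burden and the simulated symptom scores. Passing recovery tests
therefore demonstrate the correctness of the template/z-map/clustering
machinery under the stated noise model — not field performance on real DTI.

## Calibration facts used by the tests

With n controls and leave-one-out scoring, the null z is not standard
normal: z·(1+1/(n−1))^(−1/2) follows a t distribution with n−2 df, so the
sub-threshold rate at −3 is P(t₁₉ < −3/√(1+1/20)) ≈ 0.0043 at n = 21 —
about 3.2× the asymptotic Gaussian tail Φ(−3) ≈ 0.00135. The null-calibration
test compares the observed rate to this exact finite-sample value, with a
Monte-Carlo SE taken across subjects (voxel counts within a subject are not
independent evidence about the shared template). Similarly, the per-voxel
sample-SD recovery check uses the exact chi-square coverage of a ±25% band
(98.7% at n = 50) rather than an asymptotic approximation. Planted lesions of
depth 6·SD sit ~3 SD below the detection threshold, so voxel recall is near 1
and spurious clusters ≥ 10 voxels are vanishingly rare — which is why exact
per-subject count recovery is the expected outcome at these settings.

## Numerical choices and degenerate inputs

Mask coercion treats any nonzero stored value as true. Label volumes must be
integer-valued. Variance is computed from Σx² − n·mean² with a clamp at 0
against catastrophic cancellation. FA and score truncation is by clipping. A
lesion that cannot be placed without overlap after 200 retries raises. Empty
cluster lists summarize to (0, 0.0, 0.0); recovery precision under zero
detections is defined as 1.0 (no false positives were produced). Reports are
JSON with sorted keys and floats rounded to 10 decimals, making repeated
runs byte-identical under a fixed seed.

## Problem sizes

The test suite and acceptance script run on 32³ grids (~10,000 mask voxels),
21-control templates, 50-subject recovery experiments and 5,000-replicate
null simulations; these sizes give Monte-Carlo errors comfortably inside the
asserted tolerances while keeping a full run in the tens of seconds.

## Known limitations

Registration, tensor fitting, skeletonization, permutation inference and
covariate-adjusted (e.g. age-regressed) normative models are out of scope.
Only hypo-FA anomalies are detected (no high-FA direction). The summary-based
ANOVA cannot recover statistics computed on covariate-adjusted or unrounded
data — reported values that were adjusted upstream will differ from the
reconstruction, which is a property of the inputs, not an error of the
reconstruction. The choice between t and Mann-Whitney on normality grounds
is left to the caller.
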