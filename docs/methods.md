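# Methods

This note documents the models, numerical choices and known limits of the
package; nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry and containers

All grids are axis-aligned: world coordinate = `origin + index * spacing`
(voxel-center convention, 0-based indices, no rotation matrix; files with an
oblique direction matrix are rejected on ingest rather than silently
resampled). Arrays are indexed `[x, y, z]`, matching a diagonal NIfTI
affine. Interpolation is always performed in physical millimetres so that
grids with different spacing (3 mm CT slices vs 2.5 mm CBCT slices) compose
correctly. Out-of-extent samples take a type-specific background (−1000 HU,
0 Gy, mask = false) so border behaviour downstream is deterministic; all
samplers use `grid-constant` boundary handling because scipy's plain
`constant` mode is discontinuous at the last voxel, which measurably
corrupted gradient-based similarity at volume borders.

Displacement fields are dense per-voxel 3-vectors in mm with the pull-back
convention `warped(x) = moving(x + v(x))`, stored on the fixed image's grid.

## Synthetic world

The phantom is a set of analytic ellipsoids: head (soft tissue, fat shell),
cranial bone shell, spine cylinder, airway cavity, a nasopharyngeal target,
and two parotid glands lateral to it. The HU table is air −1000, fat −100,
soft 40, parotid 30, bone 700. Per-patient jitter (default ±8 % on sizes
and a few mm on centers) gives a cohort a realistic spread of gland volumes
(roughly 9–20 cc, similar to the clinical range). The default grids are
96×96×64: CT at 2.5×2.5×3.0 mm, CBCT at 2.5 mm slices. In-plane 2.5 mm was
chosen (over sub-millimetre clinical pixels) so a registration fits a desk
budget; it is configuration, not a constant.

Weekly anatomy is produced by a known smooth field composed with a random
rigid setup error (σ = 2 mm / 1°). Per gland, space contracts radially about
the *drifted* gland center by the linear scale `s = (1 − reduction)^(1/3)` —
exact inside the gland, blended smoothly to zero at 2.2 gland radii — and
translates medially; a lateral neck-thinning term compresses the body below
the skull but is shielded inside the gland support so the realized gland
volume change equals the requested one. Progression is linear in the week
index (no clinical time course was available to fit). Defaults: 13.5 %
course-total parotid volume reduction, 4 mm medial drift, 3 mm neck
thinning. Generated fields have minimum Jacobian determinant well above 0.2
(tested) and are therefore comfortably invertible; requesting ≥ 60 %
reduction is refused because the contraction would approach folding.

Masks carry an anti-aliased indicator alongside the boolean voxel
classification: `0.5 − d/ramp` clipped to [0, 1], where `d` approximates
signed distance to the analytic surface and the ramp spans twice the voxel
spacing. Warping interpolates this indicator (cubic spline) and thresholds
at 0.5. Two measured artefacts of the naive alternative (trilinear
interpolation of the binary mask) motivated this: a systematic
erosion/dilation of order `spacing²/curvature-radius` ≈ 0.2–0.3 mm per
warp, which alone broke the realized-shrinkage contract and capped
achievable Dice at ≈ 0.97, and lattice-alignment dependence of warped
volumes. Realized volume reduction is asserted on the per-course gland mean:
single-gland voxel counts at 2.5 mm carry ≈ ±1 point of counting noise.

CBCT corruption: `v·(1+bias)·scale + offset + noise`, with the bias a
white-noise field smoothed periodically at σ = 50 mm and normalised to RMS
0.05 (scatter is low-frequency: its power above 1/(2σ) is < 5 % — tested
spectrally), noise SD 20 HU, scale 0.95, offset −15 HU. These were chosen
once as values a physicist would call realistic for clinical CBCT and were
not revisited after observing their consequences (see "Honest limits").

## Registration

**Rigid.** Gradient-magnitude Pearson correlation over 3 translations + 3
rotations (about the fixed image's physical center), maximised by
deterministic multi-start Powell at quarter resolution, refined at half and
briefly at full resolution. Because `|∇(I∘T)| = |∇I|∘T` for rigid `T`, the
moving image's gradient-magnitude map is computed once and merely resampled
per candidate, which makes full-resolution evaluations cheap. Ties in the
multi-start are broken toward the smaller translation. Verified: identity to
< 0.2 mm/0.2°, a 5 mm shift to < 0.5 mm, a 3° rotation to < 0.5° (the last
requires the full-resolution polish: at half resolution the objective is
flat below ≈ 1°).

**Deformable (GFFD).** Coarse-to-fine (shrink 4/2/1). Per level:

- Descriptors: gradients of the Gaussian-smoothed image (per-axis physical
  scale; the smoothing scale expressed in mm makes the estimate consistent
  under anisotropic sampling), normalised by `|g| + ε`. ε is adaptive:
  `max(k · median|g|, 1 % of p95|g|)` per image, shared between the two
  images (max) so the descriptors remain comparable; the median term tracks
  the image's noise floor. `k` is per-level (3, 1, 8): permissive at the
  information-rich middle level, conservative at full resolution where
  noise dominates incremental gains.
- Similarity: mean squared difference of the two normalised gradient
  fields.
- Force: per channel, the difference times the average of the fixed and
  warped-moving channel gradients (bi-directional), with the demons
  per-voxel normalisation `diff/(|J|² + diff²/k²)` so weak but genuine
  edges (a 10 HU organ boundary) take steps comparable to skin or bone.
- Update smoothing: *edge-weighted normalised convolution* — the force is
  multiplied by the local edge energy, Gaussian-smoothed (per-level width
  16/8/6 mm), and divided by the smoothed weights plus a floor. Textureless
  regions thereby inherit motion from the nearest informative edges while
  already-matched edges stay put. Plain Gaussian ("fluid") smoothing of the
  force measurably stalled: it pushed matched strong edges and the
  accept/reject rule then froze weak-edge motion.
- Step control: a candidate (update capped at one voxel per iteration, then
  lightly elastically smoothed — at least half a voxel so coarse-grid
  fields stay well conditioned for inversion) is accepted only if the
  similarity strictly improves; the step grows ×1.1 on acceptance and
  halves on rejection, terminating when it collapses. Within one level the
  similarity trace is therefore monotone, and a single-level run can never
  score worse than the zero field. Across pyramid levels the guarantee is
  per-level (the upsampled initialisation is not re-compared to zero).
- Prefilter: images whose estimated noise (robust MAD of slice
  differences) exceeds 3 HU are denoised by non-local means (patch 3,
  search 5, h = 0.6σ). Patch averaging pools evidence along coherent
  surfaces and cuts the flat-region noise SD ~10× while partially
  preserving boundaries Gaussian smoothing would wash out.

**Inversion.** Fixed-point iteration `v⁻¹(x) ← −v(x + v⁻¹(x))` with
adaptive under-relaxation (halved when the update oscillates, as happens
when the field's Lipschitz constant approaches 1), run on any requested
target grid (the planning grid for dose warping). Pure translations invert
exactly; smooth fields reach composition residuals well below 0.1 voxel.
Folding fields (non-positive Jacobian) are refused.

## Dose

The engine is a declared surrogate for a clinical TPS and preserves only
the properties the accumulation pipeline exercises: density dependence
(radiological depth = cumulative relative-density line integral along
parallel rays in the axial plane), geometric sensitivity (error-function
field edges, σ = 3 mm penumbra), depth dose (linear build-up to 15 mm, then
`exp(−μ(d − d_max))` with μ = 0.005/mm — engine constants, not clinical
values), and exact linearity in beam weight. HU→density is piecewise
linear through (−1000, 0), (0, 1), (1000, 1.6), constant above. Plans
normalise so the target mean equals the prescription; the weekly
recalculation reuses the *frozen* planning normalisation factor, so
anatomical change shows up in delivered dose instead of being renormalised
away (the alternative is a config toggle). Weekly doses are warped to the
planning frame through the inverse field, scaled by
`fractions_that_week / total_fractions`, and summed.

DVH endpoints use the ≥ convention with plain voxel counting (no partial
volumes), D50 from order statistics (maximal dose received by at least half
the voxels; ties resolve toward the higher dose), Dmean as the arithmetic
mean. These definitions make brute-force oracles exact, and the test suite
holds the implementation to them exactly.

## Statistics

Paired t (`t = mean(d)/(sd(d)/√n)`, df = n−1, two-sided) with the Pearson
correlation of the two arms reported alongside; independent two-sample t
with the classical pooled variance as the primary row and Welch
(Satterthwaite df) always computed next to it; α = 0.05, no
multiple-testing correction in the primary columns (a Holm-adjusted column
is emitted, explicitly marked as an extension). Glands are the paired
analysis unit; group tables default to patient level (mean of a patient's
two glands), toggleable to gland level. Degenerate inputs (zero-variance
differences, both groups constant) surface as annotated table rows, not
crashes. p-values are verified against numerical integration of the t
density to 1e−8, and the pooled test's type-I error is calibration-tested
at 5 % ± 2 % over 2000 null replicates.

## Scaled-down experiments

The registration-validation cohort runs at the full default grid
(96×96×64). The end-to-end experiments (identity reproduction and
shrinkage/drift directionality) run at a reduced 64×64×48 grid
(3.75/4 mm) with a consistent 2-week, 20 Gy course so the whole multi-week
chain fits a desk budget; every stage is identical, only sizes shrink. The
directionality experiment additionally disables the weekly rigid setup
error: setup error physically perturbs delivered dose relative to the
fixed beam apertures with zero mean, a nuisance that averages out over a
real 6–7-week course (measured with ground-truth fields: the anatomical
effect alone is +0.45–0.51 Gy for every gland, while setup noise adds
±0.3 Gy swings per gland) but would dominate the sign at 2 weeks. The
experiment thereby isolates the systematic anatomical trend it is meant to
check.

## What a green test does and does not establish

The generator emulates: grids and slice thicknesses of a realistic
protocol, weekly smooth anatomical change of the reported magnitude, setup
error, and CBCT-like intensity corruption. It does **not** emulate real
patient texture (organs are near-homogeneous ellipsoids), imaging physics
(beam hardening, motion artifacts, truncation), fraction-to-fraction
anatomy within a week, or clinical contouring variability. Green end-to-end
tests therefore establish the *mechanics* of the chain — geometric
consistency of registration, inversion, warping, dose bookkeeping and
statistics — under a controlled world, not clinical accuracy.

## Honest limits

The contour-propagation fidelity target (cohort-mean parotid Dice ≥ 0.96,
mirroring a clinically reported validation figure) is **not met** in this
synthetic world: the measured plateau is ≈ 0.86–0.90. The cause is
information-theoretic, not algorithmic: the phantom's parotid-to-soft-tissue
contrast is 10 HU by construction while the (realistically chosen) CBCT
noise SD is 20 HU, so the gland boundary is locally invisible (per-voxel
gradient SNR ≈ 1); clinical parotid boundaries carry several times that
contrast. Three observations support this reading, all computed by the
suite or reproducible from it: (i) with identical known deformations and
no intensity corruption the same registration reaches mean Dice ≈ 0.97–0.99;
(ii) the similarity objective evaluated along the true gland displacement
has its minimum at the truth even under corruption (the estimator is
consistent; the basin is just shallow); (iii) registration error against
the generating fields stays below one voxel on average, meeting the
recovery criterion. The corresponding acceptance test asserts the stated
0.96 and is expected to fail; the threshold was deliberately not weakened.
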