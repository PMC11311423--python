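# Methods

This note documents the models and conventions the package implements, the
choices made where the problem statement was genuinely open, and what the
synthetic phantom world does and does not establish.

## Coordinate frame and data model

All volumes live on an axis-aligned voxel lattice (`ImageGrid`): the world
position of voxel index (i, j, k) is `origin + index·spacing` and refers to
the voxel **center**; spacings are mm, so anisotropic lattices are handled
uniformly and every distance below is a world-mm distance. NIfTI affines
with rotation/shear are rejected rather than resampled; negative diagonal
entries (axis flips) are rejected too, so a written-then-read grid
round-trips exactly. Dose is carried in cGy everywhere, matching the scale
on which the flagging threshold is stated.

Masks of a pair must share one lattice and are never resampled — resampling
a binary mask would itself perturb the geometric agreement being measured.
Only the dose grid is resampled (trilinearly, once per patient, shared by
both contour sets); target voxels outside the source extent get 0 cGy and a
logged count. Trilinear interpolation reproduces any globally affine dose
field exactly, which the tests exploit.

## Surface model

Surfaces are **surfels**: every face of an occupied voxel whose
6-neighbour is unoccupied — or outside the grid, so structures truncated at
the scan edge still carry a closed surface — contributes one point at the
face center weighted by the face area (mm²). Consequences:

- sDSC's numerator and denominator are exact voxelized surface areas, not
  point counts, so anisotropic voxels are weighted correctly;
- surface-to-surface distances are distances between finite point sets,
  which an exhaustive all-pairs computation can check to 1e-9 mm — the
  production paths use k-d trees and must match that oracle exactly;
- a single 1 mm voxel has 6 surfels of 1 mm² each, giving unambiguous
  hand-computable fixtures.

HD is the true maximum (100th percentile), not HD95: the long-tail
behaviour of clinically cropped tubular organs is part of the phenomenon
under study, and a percentile variant would suppress it. Identical
occupancy arrays short-circuit to (DSC, sDSC, HD) = (1, 1, 0) and mark the
pair `identical`; the identical fraction is a first-class cohort statistic
because auto-contours accepted without edits dominate real cohorts.

## Dose statistics

D0.01cc accumulates whole voxels: in-structure doses sorted descending
(ties broken by ascending linear voxel index, so results are deterministic)
until the running volume first reaches 0.01 cc; the dose of the last voxel
included is returned. No sub-voxel or DVH interpolation is applied — the
whole-voxel rule is reproducible and checkable against a brute-force
sort-and-accumulate. Structures smaller than 0.01 cc (lenses are ~0.2 cc;
synthetic organs can be smaller) fall back to the in-structure minimum with
a warning rather than erroring.

Deltas are signed auto − clinical; every summary statistic uses the
absolute value (the signed values feed only the Wilcoxon test). ΔD_CO
takes the organ's clinical-objective kind: mean dose for larynx,
submandibular glands and parotids, D0.01cc for the rest. The flag boundary
is inclusive (ΔD_CO ≥ 200 cGy). Pairs with an empty mask become
unevaluable records: excluded from every denominator, retained in the
audit trail.

## Proximity

OAR-to-PTV distance is the minimum surfel-to-surfel Euclidean distance,
clamped to 0 on voxel-wise overlap. A surface definition (rather than
centroid) is required for the statements the pipeline makes: organs
abutting or inside a PTV must read as distance 0. The 25 mm cutoff is
inclusive. The production path uses a k-d tree over PTV surfels; the
brute-force oracle is retained in the tests.

## Statistics

- **Quantiles**: linear interpolation between order statistics, stated once
  and used everywhere (median, Q90, the pooled 10th/90th-percentile
  coverage thresholds).
- **Wilcoxon signed-rank**: two-sided, Pratt zero handling — zeros are
  ranked with the rest and then dropped from the statistic. With a
  majority of exactly-zero deltas, classic zero-dropping would discard most
  of the sample and overstate significance. For ≤ 15 nonzero deltas the
  null distribution of W⁺ is computed exactly by convolution over doubled
  (tie-averaged) ranks — equivalent to enumerating all 2ⁿ sign
  assignments, which the tests do independently; larger samples use the
  normal approximation with tie correction (scipy, no continuity
  correction).
- **R²**: ordinary least squares of the absolute dose difference on the
  geometric index. Constant response (all-identical strata) is defined as
  R² = 0 rather than undefined; fewer than 3 points yields null.
- **Binned curves**: half-open bins [lo, lo+w) with the top DSC/sDSC bin
  closed at 1.0; empty bins are reported with null fractions so the
  curve's support is explicit. Bin widths: 0.1 for DSC/sDSC, 2 mm for HD.
- **Sensitivity scenarios**: (a) restrict to prescriptions ≥ 4000 cGy;
  (b)/(c) replace the absolute threshold with 3 % and 5 % of each
  patient's prescription. Scenarios operate on record copies so the
  baseline flags are never clobbered.

## The synthetic phantom world

No patient data ship with the package, so the generator states a world and
the tests measure it:

- 100×100×70 voxels at 2 mm isotropic (200×200×140 mm); one spherical PTV
  (radius 25 mm) prescribed 6996 cGy — the typical head-and-neck
  69.96 Gy/33-fraction prescription.
- Dose: prescription plateau inside the PTV, `Rx·exp(−d/λ)` outside with
  λ = 5 mm (a steep clinical-order fall-off), clamped at a 30 cGy scatter
  floor; optional truncated-Gaussian noise, off by default. Distances use
  an anisotropy-aware Euclidean distance transform.
- Eight template organs drawn from the 19-OAR vocabulary span three
  distance classes: abutting/overlapping (Brain, Parotid_L), within 25 mm
  (Brainstem, Cochlea_L, Larynx tube), beyond 50 mm (Eye_R,
  Glnd_Submand_R, SpinalCord tube). Near-class organs sit **inside the
  dose gradient** (surface gaps ~8–10 mm): at λ = 5 mm an organ 15–25 mm
  out already sees only the scatter floor, and a "near" class placed there
  would be dosimetrically indistinguishable from the far class — whereas
  the clinical cohorts this emulates show flagged small organs with
  clinical-objective differences of hundreds of cGy, which only
  in-gradient placement produces.
- Perturbations: 57 % of pairs are bit-identical (the observed fraction of
  auto-contours used as-is); the remaining 43 % split over dilation and
  erosion by 1–2 voxels, whole-voxel translations of 4 and 8 mm, axial
  truncation of the top 40 % of occupied slices (the planner-cropping
  pattern of tubular organs) and deletion of 2 interior slices (the
  forgotten-interpolation error). Magnitudes act in voxel units converted
  from mm so fixtures stay exactly reproducible. If a sampled erosion
  would empty a mask the generator deterministically downgrades to
  erosion-by-1, then identity; `perturb()` itself raises instead of
  returning an empty mask.
- Determinism: geometry (grid, templates, dose) is fixed by the config;
  only perturbation draws consume randomness, so changing the seed changes
  which contours are edited, never the anatomy.

What a green cohort-level test establishes: the pipeline reproduces, on a
world with a steep monotone gradient and size-spanning organs, the
qualitative structure of real cohorts — a decreasing flagged-proportion
trend over DSC bins, concentration of flags near the target, zero flags in
the far field, and the two deceptive regimes (high DSC flagged at the
target; low DSC harmless in the flat field). What it does not establish:
quantitative fidelity to any clinical cohort. The phantom has one PTV, one
prescription, convex organs, no inter-patient anatomical variation, a 2 mm
lattice (coarse relative to lens-scale structures, which is why sDSC drops
to 0 for heavily eroded small organs — every surfel moves > 2 mm), and an
idealised exponential dose model rather than a planned VMAT distribution.
Cohort-level numbers from it (flagged fractions, coverage thresholds, R²)
characterise the phantom, not clinical practice.

## Illustrative fixtures

Fixture A (high agreement, large dose error): a brain-like organ abutting
the PTV whose auto version adds a small protrusion reaching into the
plateau/gradient — DSC ≈ 0.998 yet ΔDmax ≈ 3850 cGy, flagged. Fixture B
(low agreement, no dose error): a cochlea-like organ 20 mm out in the
flat region, auto version eroded by 2 voxels — DSC ≈ 0.13 yet
ΔDmax < 100 cGy, unflagged. B sits at 20 mm deliberately: it is *within*
the 2.5 cm cutoff, making the point that proximity flags candidates for
review rather than condemning them.

## Known limitations

- NIfTI only; no DICOM RTSTRUCT/RTDOSE ingestion or polygon rasterization.
- Axis-aligned volumes only (rotated/flipped affines rejected, not fixed).
- Whole-voxel D0.01cc differs from planning systems that interpolate DVHs;
  differences are sub-voxel-dose-sized.
- The Wilcoxon exact path is O(n · Σrank) via convolution — fine for the
  ≤ 15 crossover, not intended for large exact computations.
- Translation perturbations near the grid edge clip rather than wrap;
  clipped content simply counts as edited volume.
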