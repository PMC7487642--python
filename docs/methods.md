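# Methods

`orbitmorph` re-implements, as an open and testable pipeline, a 3D
workflow for quantifying orbital-cavity volume and shape change between
two CBCT acquisitions of the same patient (before and six months after
rapid maxillary expansion with a tooth-borne, TB, or bone-borne, BB,
appliance). No clinical images are distributed with studies of this
kind, so the pipeline ships a first-class synthetic phantom generator
with analytic ground truth; every stage is validated by parameter
recovery against that truth.

## Pipeline

For each subject and each time point (T1 baseline, T2 follow-up):

1. **Segmentation.** The orbital soft-tissue content is segmented by
   front propagation from seed voxels: the Eikonal equation is solved by
   first-order upwind fast marching (SimpleITK) with speed
   `F(x) = exp(-beta |I(x) - I_seed|)` inside an intensity window
   `[lo, hi]` and `F = 0` outside it, so bone and air are impassable.
   The mask is every voxel with arrival time below the cap `tau`.
   Window, `beta` and `tau` live in run configuration, never in code.
2. **Mask clean-up and surfacing.** Morphological opening and closing
   with a ball of configurable metric radius (default 0.6 mm), then a
   marching-cubes isosurface at 0.5 of the binary field, in world mm.
   The pipeline applies a Gaussian pre-smoothing of 1.0 voxel to the
   binary field before the isosurface: a binary field carries a
   half-voxel staircase that would dominate sub-voxel deviation
   measurements; the smoothing suppresses it at a curvature-bias cost of
   a few microns at the curvatures present here (and the bias cancels
   between T1 and T2 in every difference measure).
3. **Rigid registration (T1 fixed).** Iterative closest point with
   area-uniform samples on the moving (T2) surface and exact
   point-to-triangle closest points on the fixed (T1) surface, rigid
   updates by the SVD (Kabsch) solution, centroid initialisation.
   Robustness and precision come in three stages (see below).
4. **Landmark cropping.** The anterior plane is defined by the
   frontozygomatic suture (FZS), supraorbital foramen (SF) and anterior
   lacrimal crest (ALC); the posterior plane by the optic-canal points
   OC1/OC2/OC3. Both planes are picked on T1 and applied to the
   registered T2 model (deterministic plane transfer). Clipping keeps
   the slab between the planes and re-caps each intersection loop by
   ear-clipping (centroid-fan fallback), so every model stays watertight.
5. **Deviation analysis.** 50 000 area-uniform samples on the cropped
   registered T2 surface; each sample gets an exact signed
   point-to-triangle distance to the cropped T1 surface
   (angle-weighted pseudo-normal signing; positive = outside = local
   expansion). The matching percentage at tolerance `t` is
   `100 x #{|d| <= t}/n`, boundary inclusive, at the two clinical
   tolerances A = 0.20 mm and B = 0.40 mm.
6. **Volumetry.** Divergence-theorem volume `V = |sum v1.(v2 x v3)|/6`
   on the closed cropped meshes, reported in cm^3 to two decimals.
   The maxillary palatal width is the distance between the hard-palate /
   lingual-alveolar junction points picked on one coronal slice per
   scan; its T2-T1 difference is the skeletal expansion.
7. **Statistics.** Shapiro-Wilk normality; paired t (T1 vs T2 volumes);
   pooled-variance unpaired Student's t between groups (Welch by flag —
   the group SDs 0.07 vs 0.22 cm^3 are grossly unequal, so sensitivity
   to the pooling assumption must be probeable); OLS regression of
   volume change on palatal expansion with r, r^2, standardised beta and
   the 95% slope CI; two-way mixed-effects absolute-agreement
   single-measure ICC and Dahlberg's error `sqrt(sum d_i^2/2n)` for
   duplicate readings; and the noncentral-t power of the two-sided
   pooled two-sample test.

## Registration detail

Rigid alignment must not absorb the very signal the deviation stage
measures: the T2 wall carries genuine anatomical change, concentrated
but large in area, and a least-squares rigid fit happily "explains" part
of a one-sided deformation by sliding along shallow pose modes.  Three
mechanisms keep the fit anchored to unchanged anatomy:

* **Annealed trimming** during point-to-point iterations: a fixed worst
  fraction (10%) is always dropped, and once the fit tightens the cutoff
  follows `2.5 x` the previous kept RMS down to a floor of 0.20 mm, with
  a guard that at least 35% of correspondences are kept.
* **Point-to-plane refinement**: Gauss-Newton iterations on residuals
  projected onto fixed-surface normals.  Surface-extraction ripple is
  zero-mean along the normal, so this stage pins translation and
  rotation roughly an order of magnitude more precisely than
  point-to-point correspondences.
* **Deformation-patch exclusion**: signed residuals averaged over each
  sample's 40 nearest neighbours separate coherent anatomical change
  from zero-mean ripple; samples whose smoothed residual exceeds
  0.025 mm are excluded and the pose re-fit.

On calibrated phantoms the registered pose recovers the applied motion
to a few hundredths of a millimetre in the directions that matter for
volumetry and deviation (the residual azimuthal component is degenerate
only to the extent the anatomy itself is near-symmetric).

## The phantom generator

Each subject is an elliptic-paraboloid cavity (posterior apex, wide
anterior aperture; axis along +y) of soft-tissue intensity, enclosed by
a bone shell and surrounded by air:

* In scaled coordinates `x' = (x-cx)/sx`, `z' = (z-cz)/sz` (with
  `sx sz = 1`, section axis ratio 1.10) the wall is
  `rho'^2 = c (y - ya0)`. The mild ellipticity exists because a pure
  surface of revolution would leave the azimuth of any rigid
  registration unconstrained — real orbits are not symmetric.
* **Wall relief ("texture")**: 40 Gaussian features per subject
  (amplitude up to 2.0 mm, extent 1.8 mm), drawn per subject and shared
  identically by T1 and T2. They play the role of the fissures and
  fossae that anchor surface registration on real orbital walls; without
  them the smooth quadric admits shallow pose modes along which a
  rigid fit can drift at the 0.05 mm level, which is fatal to a
  tolerance count at 0.20 mm.
* **Deformation**: T2 subtracts Gaussian bumps (outward positive) from
  the implicit field, placed near the frontozygomatic and
  frontomaxillary aspects of the rim where the clinical colour maps
  localise post-expansion change. Default relative amplitudes (1.0,
  0.85); the calibration routine scales them (for a target volume
  increment) or solves their extent (for a target within-tolerance
  fraction — solving the extent keeps the displacement steep where it
  crosses the tolerance, which makes the recovered fraction robust to
  micrometre-scale registration residual).
* **Time-point differences**: after deformation the whole T2 anatomy is
  moved by a small rigid offset (default 2-2.5 degrees per axis,
  1-1.5 mm translations — repositioning between scans), and each volume
  gets fresh Gaussian intensity noise (sd 30 on air/soft/bone means
  50/600/1600).
* **Intensities** are mapped from the gradient-normalised implicit field
  with one-voxel-wide transitions (partial-volume emulation), so the
  window edge of the fast-marching stage crosses exactly at the true
  surface.
* **Per-subject variation**: cavity volume jitter (cv 7%, matching the
  relative spread of the published T1 volumes), palatal expansion drawn
  per subject (TB 1.83 +- 0.42 mm, BB 2.2 +- 0.33 mm).
* **Landmarks** are emitted by construction on the crop-plane rims
  (landmark picking was manual in the clinical workflow and is not
  re-implemented); both planes are perpendicular to the cavity axis.

Ground truth is computed from the implicit geometry, not from any voxel
or mesh stage being validated: cropped volumes by star-shaped radial
quadrature (Gauss-Legendre in y, periodic trapezoid in azimuth, with a
vectorised bisection for the wall radius — along a fixed ray the squared
distance to each Gaussian centre is a quadratic in r, so bisection steps
are pure arithmetic), and within-tolerance surface fractions by dense
parametric sampling of the T2 surface with exact point-to-triangle
distances to a fine triangulation of the T1 surface. An independent
second route (marching cubes of the implicit field at 4x grid
resolution, divergence-theorem volume) cross-checks the quadrature truth
to within 1% in the tests.

Calibration targets are population means, so calibration truth is
averaged over three fixed wall-relief draws; it is fully deterministic.

## Problem sizes and study conditions

The default phantom mirrors the clinical acquisition (0.3 mm isotropic
voxels) with a 24 cm^3 cavity on an auto-sized grid. The validation
cohorts are desk-scaled: a ~3.2 cm^3 cropped cavity on a
112^3 grid at 0.3 mm, which a single CPU can sweep a hundred
times, while the deformation targets stay at the printed clinical scale
(increments 0.64 and 0.77 cm^3; tolerance-A/B fractions 83.84% and
94.46%). Desk-scaling inflates the deformed fraction of the surface
relative to the clinic, which makes the registration problem *harder*
than the real one — recovery under these conditions is the conservative
check. Cohort sizes follow the study design: 40 orbit models per group
for volumetry, 10 pairs per tolerance for the matching recovery.

## What the phantoms do not emulate

DICOM acquisition physics (beam hardening, scatter, metal artifacts),
anatomically accurate orbital topology (the real orbit opens into the
optic canal and fissures; the phantom is closed), manual landmark
picking variability, and growth between time points. Passing recovery
tests therefore demonstrates correctness of the measurement chain under
known geometry and realistic noise — not clinical accuracy on real
anatomy.

## Numerical choices

* Fast marching: out-of-window speed floored at 1e-12 (arrival > 1e9
  anywhere outside the window), `tau = inf` clamped to 1e6; single
  ITK thread for bit-reproducibility.
* Closest-point queries: KD-tree over triangle centroids plus a
  barycentric sample lattice on oversized triangles (planar cap fans),
  exact Voronoi-region point-to-triangle minimisation over candidates.
* Clipping: slice, snap coincident cut vertices (1e-7 rounding), cap by
  ear clipping; a centroid-fan fallback handles numerically nasty
  loops; every clip is verified watertight.
* Boundary-inclusive tolerance counting (`|d| <= t`), declared for
  bit-reproducibility.
* All randomness flows from explicit integer seeds (phantom, sampling,
  ICP); regenerating a phantom with the same seed is bit-identical.

## Known limitations

* The deviation direction is fixed (samples on T2 against T1 as
  reference); the clinical software's convention is unknown, and the two
  directions differ at second order in curvature.
* The ICC model is fixed to two-way mixed / absolute agreement / single
  measure; the clinical report does not state which form was used.
* Whether registration preceded or followed T2 cropping in the clinical
  workflow is not stated; this pipeline registers the uncropped T2
  model, then crops.
* Matching percentages at 0.20 mm are intrinsically sensitive: with the
  published fractions, a systematic 0.01 mm distance offset moves the
  percentage by roughly 0.8 points, independent of scale. That is a
  property of the published quantity, not of this implementation.
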