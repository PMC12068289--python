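# Methods

This note documents the models, parameters and numerical choices behind
`aaaquant`, and what the synthetic phantoms do and do not establish about
real scans.

## Phantom model

The aneurysmal aorta is an axisymmetric tube whose outer radius follows a
Gaussian fusiform bulge

    r_out(z) = r_neck + (r_sac − r_neck) · exp(−(z − z_MAS)² / 2σ_b²),

so the maximal-radius slice coincides with the MAS landmark by construction
and an analytic per-slice radius oracle exists.  World frame: mm; +x
subject-left, +y anterior, +z superior; the tube axis is x = y = 0.

Defaults (one synthetic "study subject"): 96×96×128 grid at 0.5 mm,
r_neck = 13 mm, r_sac = 20 mm (5.6 cm total diameter — in the 4.9 ± 0.8 cm
range typical of moderately sized AAAs), bulge σ_b = 6 mm, landmarks
HRA/LRA/MIRA/MAS at z = 54/48/34/16 mm.

Two thicknesses are deliberately distinct:

* `wall_thickness_mm = 8` — the imaging wall compartment.  This models the
  peri-luminal ROI a reader contours on CTA, which includes the mural
  thrombus region, not the bare 1.5–2 mm arterial wall.  It is 16 PSF sigmas
  thick, which is what makes uncorrected wall-activity recovery meaningful
  (see *Partial volume* below).
* `mesh_thickness_mm = 2` — the mechanical wall used by the FEA, at the
  literature value for aneurysmal wall thickness.  The mesh is the wall
  mid-surface (outer radius minus half the mechanical thickness), the
  standard membrane-shell convention, with both end rings flagged as
  clamped boundaries.

PET simulation assigns blood-pool activity (0.9 kBq/mL) to the lumen,
quadrant-dependent activity to the wall (posterior 3.0 > left 2.7 >
right 2.4 > anterior 2.1 kBq/mL, the posterior-dominant pattern), and
background 0.15; convolves with an isotropic Gaussian PSF (σ = 0.5 mm, one
voxel); and adds seeded additive Gaussian noise (σ = 0.3, 10% of peak wall
activity).  Additive Gaussian rather than Poisson noise reflects
reconstructed (post-filtered) PET statistics and keeps recovery tolerances
analytic.  The pre-blur ground truth is returned alongside the simulated
volume, so every downstream statistic has an exact reference.  A run is
fully determined by (spec, seed).

At 80 kg body weight and 350 MBq injected dose these activities put
SUV_diff in the 0.2–0.7 range where clinical CCR2 wall signals are reported,
so the configurable high/low threshold (default 0.53) operates on a
realistic scale.

What the phantom does *not* emulate: tomographic acquisition and
reconstruction (the PSF stands in for resolution loss), attenuation, motion,
a distinct intraluminal-thrombus compartment, non-circular lumens, and
renal-artery anatomy (landmarks are inputs, not detected).  Passing recovery
tests therefore demonstrates correctness of the quantification pipeline
under idealized resolution/noise conditions, not clinical accuracy on
patient scans.

## Segmentation

For each landmark L at z_L with slab half-width h (default 5 mm; 2 mm in
the compact demo configurations): "Ab L" = [z_L+h, z_L+3h), "L" =
[z_L−h, z_L+h), "Be L" = [z_L−3h, z_L−h), half-open in slice centers, so
adjacent slabs never share a slice.  Slabs truncated by the grid are logged
and empty slabs propagate as *missing* table cells (statistics NaN, never
zero) — mirroring measurements that are anatomically unavailable in some
subjects.

Blood pool = lumen eroded by a spherical structuring element of the erosion
radius (default 2 mm), guaranteeing every blood sample voxel is at least
that far from the wall; with a 0.5 mm-PSF this is ≥ 4σ, so the blood
reference is effectively uncontaminated.  Quadrants are assigned per slice
by the angle of (voxel − lumen centroid), measured from +y (anterior)
toward +x (left): anterior [−45°, 45°), left [45°, 135°), posterior
[135°, 225°), right [225°, 315°) — half-open, so a voxel at exactly 45°
is *left*.  The per-slice lumen centroid (not a global centerline) defines
the sector origin; for strongly tortuous vessels a centerline would be
preferable, which is a known limitation.  When no labels are provided,
lumen extraction from CTA thresholds at HU > 150, keeps the largest
connected component, and takes a configurable band outside the lumen as the
wall ROI.

## Uptake statistics

SUV uses the body-weight convention.  One global blood-pool mean per
subject is subtracted from wall means and maxima (a scalar blood reference
is the only consistent reading of "max SUV_diff").  Quadrant statistics
pool the wall voxels of the MAS area (the three MAS slabs).  The *MAS
cumulative uptake value* is the voxel-count-weighted mean of mean SUV_diff
over Ab MAS / MAS / Be MAS — identical to the voxel-wise mean over their
union (asserted in tests); unweighted mean and sum are available since
"cumulative" admits several readings.  Classification: high ⇔ value ≥
threshold (deterministic boundary rule).

### Partial volume

No partial-volume correction is applied.  With the PSF at one voxel and the
8 mm wall band, the residual wall-SUV_diff underestimation is ≈ 6–8%
(reported per run by the acceptance script as `suvdiff_worst_rel_bias_pct`);
it grows roughly like 0.2·σ_PSF/half-thickness × (1 + contrast ratio), so
thin-wall configurations underestimate much more strongly.  The bias is
measured and reported, never corrected.

## Wall stress, strength and RPI

**Membrane FEA.**  Constant-strain triangles on the mid-surface with the
plane-stress constitutive law, thickness-scaled stiffness, and consistent
pressure loading along outward facet normals; clamped (all-DOF) boundary
rings; sparse direct solve.  Element von Mises stress is averaged onto
nodes with area weights.  Defaults E = 2.7 MPa, ν = 0.49 (near-incompressible
arterial tissue); for a statically determinate membrane the stress field is
insensitive to E, and this insensitivity is itself a test.  Stress
converges under refinement; at the 64×64 reference mesh the cylinder and
sphere benchmarks agree with the Laplace closed forms to ≈ 0.1–0.2%.

Benchmark boundary conditions deserve care:

* *Cylinder*: clamping **one** end ring leaves the far edge traction-free,
  so the net axial force vanishes and the mid-span state is pure hoop,
  σ = P·r/t.  Clamping both rings would impose axial compatibility and add
  σ_axial ≈ ν·P·r/t, shifting von Mises to ≈ 0.87·P·r/t — a different,
  equally valid benchmark, but not the Laplace hoop form.
* *Sphere*: a closed surface has no boundary ring; six rigid-body
  constraints are placed at three extremal nodes, each restraining only the
  two tangential directions so the uniform breathing mode (the exact
  solution) is unconstrained.  Meshes with no flagged boundary nodes get
  this restraint automatically.

**Shoulder stress.**  For a steep fusiform bulge the membrane solution puts
peak stress at the bulge *shoulders*, not the equator: the dome-like
meridional curvature at the sac carries part of the pressure spherically
(lowering equatorial hoop stress), while the concave meridian at the
shoulders raises it.  The "largest radius ⇒ largest stress" Laplace
ordering holds only for gently tapered sacs (bulge σ_b ≳ 2·r_sac), and the
peak-RPI-at-MAS property is asserted in that regime.  Similarly, a
cross-sectional bump raises a quadrant's mean stress only when it is narrow
enough to fit inside the quadrant; a wide bump flattens (and loads) the
flanking quadrants instead.

**Strength.**  S = 71.9 − 37.9(√ILT − 0.81) − 15.6(NORD − 2.46) −
21.3·HIST + 19.3·SEX [N/cm²] — the noninvasive statistical wall-strength
model from the AAA rupture-potential literature, shipped as a versioned,
overridable YAML coefficient file (`data/strength_coefficients.yaml`), not
hard-coded.  Covariate coding: NORD = max sac diameter / infrarenal neck
diameter; HIST = 1 with family history else 0; SEX = +1/2 male, −1/2
female; ILT (intraluminal thrombus thickness, cm) is an optional per-node
covariate defaulting to 0 since the phantom has no thrombus compartment.
Strength is spatially constant without ILT, hence exactly invariant under
mesh refinement.

**RPI** = stress / strength per node; dimensionless; RPI = 1 where stress
equals strength; exactly linear in pressure (linear FEA, constant
strength).  With the default phantom (2 mm mechanical wall, 120 mmHg,
r_sac = 20 mm) peak RPI is ≈ 0.1 — scaled down from clinical values (≈ 0.3–1
for large thin-walled sacs) because the phantom's sac is modest; the RPI
*machinery* (definition, linearity, co-registration) is what the phantom
validates, not patient-level risk magnitudes.

**Units.**  All conversions (mmHg ↔ Pa ↔ N/mm² ↔ N/cm²) go through
`aaaquant.units` with a single constant (1 mmHg = 133.322365 Pa); round
trips are exact to 1e−12 relative.

## Co-registration

Each mesh node maps to the voxel whose center is nearest (ties — exact
half-spacing coordinates — resolve to the lower index per axis, i.e. the
lowest linear index).  Painted intensity = offset + scale·RPI with
offset = max(CTA) + 3·SD(CTA), strictly above the background; voxels
receiving several nodes carry their mean RPI, and un-painting
((v − offset)/scale) recovers those means exactly.  Resampling onto the PET
grid uses a known rigid transform and nearest-neighbor interpolation — RPI
intensities are codes, not densities; linear interpolation would fabricate
intermediate RPI values.  The phantom pipeline uses the identity transform
(shared grid); the rigid path is exercised with synthetic known transforms.
Quadrant RPI aggregation reuses the *identical* sectoring labels as the
uptake analysis, so SUV–RPI correlations compare aligned sectors.

## Statistics

Welch's unequal-variance t-test for two groups (group SDs of this kind of
data are visibly unequal), one-way ANOVA for three or more; identical
constant groups return p = 1 with a degeneracy flag.  The SUV–RPI
association pools (subject, quadrant) pairs in a Pearson correlation
(Spearman by configuration).  No multiple-testing correction by default
(per-contrast reporting); Bonferroni by flag.  Missing cells are excluded,
never imputed.

The summary-level cohort generator draws paired quadrant values as a fixed
posterior-dominant quadrant-mean profile (shared, up to scale, by SUV_diff
and RPI) plus independent Gaussian subject noise, with the variance split
so the population correlation equals the designed r exactly
(signal share = r in each modality).  Because the signal component is fixed
by design, the sampling variance of r̂ is smaller than for an unstructured
bivariate normal sample of the same size; at r = 0 the profiles are flat
and the generator yields the null cohort on which the type-I error of the
correlation test is calibrated.  The full-imaging cohort
(`aaaquant cohort`) instead varies uptake and geometry independently, so
its quadrant SUV–RPI correlation is near zero on axisymmetric phantoms —
the designed-correlation generator exists precisely to test the recovery
machinery at a known effect size.

## Problem sizes and determinism

The shipped configurations are sized for interactive runs: benchmark FEA
ladders up to 64×64 elements, 100-seed recovery ensembles on the default
phantom, 200-seed correlation and 1000-seed null calibrations at the
summary level.  Every stochastic component takes an explicit seed; the CLI
writes a manifest with output checksums, and identical (config, seed) runs
are checksum-identical.

## Known limitations

* Membrane-only shell (no bending): boundary-layer effects at clamped rings
  are mesh-local and excluded from benchmark readouts; bending-dominated
  features (sharp necks, calcifications) are out of scope.
* Per-slice centroid sectoring assumes near-axial vessel orientation.
* The strength model's coefficients are population-level regression values;
  per-patient strength is not identifiable from imaging alone.
* No partial-volume correction (measured, reported, uncorrected).
* Registration is a known rigid transform; estimating the transform
  (mutual-information registration) is out of scope.
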