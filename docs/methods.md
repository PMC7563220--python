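# Methods

## Scientific question and study design

Deep pelvic hyperthermia treatment planning predicts the specific
absorption rate (SAR) a phased-array applicator deposits in a patient
model, then optimizes per-antenna amplitudes and phases to heat the tumor
while sparing healthy tissue.  The prediction depends on how many tissues
the patient model discriminates: a clinical protocol segments only
fat-like, muscle-like, bone and tumor, while a detailed model separates
urine, bladder wall, intestine walls and lumina, bone compartments, and
more.  This package quantifies the cost of that simplification *in a
relative design*: the detailed model is the benchmark; every reduced
segmentation is compared against it with the drive settings frozen.

For each tumor site and gross target volume (GTV) size:

1. generate the detailed phantom;
2. solve one steady-state complex E-field per antenna channel;
3. optimize the channel weights to maximize THQ on the detailed model;
4. re-solve the fields for each reduced segmentation (the materials change
   the electromagnetic solution) and re-apply the *frozen* drive;
5. score the reduction with |dTHQ| and per-tissue |dRD|.

Aggregation follows the summary-table convention: per site and scheme, the
maximum |dTHQ| across the three GTV sizes, reported next to the standard
deviation across sizes; per-tissue |dRD| is summarized as median, quartiles
and 2.5/97.5 percentiles (linear interpolation between closest ranks).

## Dose metrics

* SAR = σ|E|²/(2ρ) with E the peak phasor (vector norm over components).
  The statistic is a volume-percentile mean; no IEEE-style 1 g/10 g mass
  averaging is applied anywhere.
* THQ = mean SAR in the hyperthermia target volume (HTV) ÷ mean SAR of the
  hottest 1 % of healthy-tissue volume (labeled body excluding the HTV).
  The hotspot selects the ceil(0.01·N) top voxels; the fraction is
  configurable.  THQ is invariant under global amplitude scaling and
  global phase rotation of the drive.  A fully uniform SAR distribution is
  detected as a degenerate case and returns exactly 1.
* |dTHQ| (%) = |(THQ_n − THQ_ref)/THQ_ref|·100 against the detailed
  benchmark; values at or below 5 % are flagged "below clinical
  relevance", the threshold corresponding to a ~0.2 °C change in simulated
  median target temperature reported in the treatment-planning literature
  (applied as a cited constant, never recomputed here).
* per-tissue |dRD| (%) — the same relative difference applied to the
  maximum average SAR (mean over the hottest 1 % of that tissue's
  volume).  Tissue masks are always cut from the *detailed* labels so all
  schemes are scored on identical regions; a tissue with zero reference
  SAR is flagged undefined and excluded from summaries with a warning.
  |dRD| is judged against a 0–20 % band.

## Tissue model

The registry ships the 14-tissue dielectric table at 100 MHz (relative
permittivity, effective conductivity in S/m, mass density in kg/m³) used
by every simulation; the tumor row is fixed (εr 70.0, σ 0.750, ρ 1050) and
the large-intestine lumen carries muscle-identical constants, exactly as
tabulated in the source database.  Two conventions are structural:

* urine is assigned muscle-equivalent properties in every scheme that does
  not delineate the bladder (the clinical empty-bladder assumption);
* subcutaneous (SAT) and visceral fat are distinct anatomical labels that
  share the fat properties, implemented as a property alias so the
  "detailed" scheme remains a strict identity mapping.

Seven segmentation schemes are generated programmatically and shipped as
JSON: detailed (identity), clinical (high-water→muscle, low-water→fat,
bones→cortical bone), bone_type, bladder, intestine, bladder_and_intestine
and combined.  GTV is preserved by every scheme.  Scheme application is
idempotent, and the combined retained set is the union of the bone_type,
bladder and intestine retained sets.

**Degeneracy worth knowing:** with the default 13-label phantom anatomy the
combined scheme retains every structure the phantom has, so it is
materially identical to the detailed benchmark and its |dTHQ| and |dRD|
are exactly zero.  This is a faithful consequence of the phantom design
(the benchmark need only be strictly richer than the *reduced* schemes);
adding user-supplied extra organ labels (with their own properties and
water-content class) breaks it.

## Synthetic phantoms

Licensed whole-body anatomies cannot be redistributed, so the phantoms are
procedural: an elliptical-cylinder torso (default semi-axes 150 × 105 mm,
300 mm long) with a SAT shell, muscle bulk, a posterior spine and two
lateral bone columns (cortical shell / cancellous interior / marrow core),
a bladder (one-voxel wall closed around the urine volume by construction),
small- and large-intestine loops built as seeded random-walk tubes
(wall around lumen), visceral fat pockets, and a GTV ellipsoid at a
cervix-, prostate- or rectum-like position in three nested sizes (12, 17,
22 mm base radius).  The HTV is the GTV dilated by a 10 mm isotropic
margin (configurable; the margin is a declared default, not a literature
value) and is an evaluation region only — HTV voxels outside the GTV keep
their tissue labels.

A requested fat fraction sets the SAT thickness analytically; the torso
radii scale with fatness so the inner muscle compartment — and the organ
layout — stays nearly constant across a cohort.  The realized fat
fraction lands within ±3 percentage points of the request at the default
5 mm spacing.  The default fat fraction (0.37) and the population range
(0.25–0.55) bracket the published fat/muscle compositions of both
treated-patient and virtual-model cohorts; over a generated cohort the
muscle%-vs-fat% OLS regression reproduces the expected near-perfect
anticorrelation (R² ≈ 0.99).

Coordinates: 0-based voxel indices, axes (x left-right, y
anterior-posterior with +y posterior, z caudal-cranial), isotropic
spacing, world mm from the origin corner.  Grids are odd-sized with a
voxel center on the torso axis so left-right symmetric anatomy is
symmetric on the grid — this is what makes the mirror-symmetry solver
tests exact.  Phantoms are deterministic given (params, seed) and are
written/read as NIfTI with a JSON sidecar.

What the generator does *not* emulate: statistical shape variation, CT/MR
image formation, gastrointestinal air (deliberately absent), posture, and
the ~80-tissue granularity of licensed models.  Passing tests therefore
demonstrate the *method chain* — solver physics, metric arithmetic,
optimizer behavior, directional segmentation effects — not the clinical
magnitude of any particular |dTHQ| value.

## Electromagnetic solver

A finite-difference time-domain solver with a convolutional PML (8 cells,
cubic conductivity grading with σ_max = 0.8(m+1)/(η₀Δ), linear α ramp,
κ = 1) on all boundaries.  Two paths share the infrastructure:

* **2D TMz** (the production/test path): Ez at cell centers, twelve line
  sources on a ring; the phantom's axial slice through the GTV centroid is
  embedded in a water bolus inside the applicator shell, exterior free
  space.  Desk-scale domains are ~150² cells at 5 mm.
* **3D Yee** (coarse): node-based staggering, three axial rings of four
  3-cell z-oriented soft dipoles.  The exact geometry of any commercial
  applicator is proprietary; this generic layout stands in, which is
  admissible because every study conclusion is relative (detailed vs
  reduced on identical geometry and grid).

Time step = 0.95 × the Courant limit, rounded so an integer number of
steps tiles one drive period.  Each channel is driven individually at unit
amplitude for 15 periods of the 100 MHz harmonic (the source amplitude
ramps over 3 periods with a raised cosine to suppress transients), and the
phasor is extracted by projecting onto e^{−jωt} over exactly the final
period.  The steady-state residual (final vs penultimate period) is below
1 % RMS at the default settings.  Divergence (non-finite or exploding
fields) raises a solver error citing the time step.

Validation oracles: the fitted attenuation and phase constants in
homogeneous muscle match γ = √(jωμ₀(σ+jωε)) to ~0.2 % (α ≈ 13.0 Np/m,
β ≈ 21.4 rad/m at the tabulated muscle constants); a vacuum line source
follows the 2D free-space Green's function |H₀⁽²⁾(kr)| to < 1 %; discrete
superposition of simultaneous drives is exact to machine precision; and
mirrored channels produce exactly mirrored fields on symmetric fixtures.
An optional numba kernel accelerates the 2D path ~7×; the pure-numpy loop
is the reference implementation and is used automatically when numba is
absent.

## Drive optimization

Global-best particle swarm over n amplitudes in [0, 1] and n−1 phases
(one channel gauge-fixed to phase 0; THQ is invariant under a global
phase).  Amplitudes reflect off the box walls, phases wrap circularly and
attractor pulls take the short way around the circle.  Defaults: 40
particles, 150 iterations, inertia 0.72 with 0.995 decay, cognitive and
social coefficients 1.49 — conventional constriction-style values; no
published hyperparameters exist for clinical planning tools.  The
all-equal-weights drive is injected as one initial particle, so the
returned THQ can never fall below that baseline.  Setting the amplitude
bounds equal pins the amplitudes and searches phases only, which is how
the optimizer is compared against the exhaustive 5°-phase-grid oracle on
the 3-channel disk fixture.

On the symmetric 12-channel disk the equal-phase drive and the swarm's
unconstrained optimum agree to ~1e-4 relative; the residual comes from
rounding source positions to grid cells, which breaks continuum rotational
symmetry and leaves near-flat collective phase directions.  Phase-recovery
accuracy is therefore asserted against the oracle-certified optimum of the
3-channel reduction, not against the 12-channel landscape.

## Numerical choices and degenerate inputs

* Hotspot means select ceil(f·N) voxels via partition + sort of the top
  block, so the result is bit-identical to a full-sort oracle; ties share
  a value, so any tie-resolution yields the same mean.
* Percentiles use linear interpolation between closest ranks (the numpy
  default), declared because boxplot statistics depend on the rule.
* Zero drive yields an identically zero field; THQ of a zero field raises
  (0/0); |dRD| with a zero reference is flagged undefined, warned about,
  and excluded from summaries; a degenerate (zero-width) fat-fraction
  range yields NaN regression with a warning.
* The standard deviation across GTV sizes is the sample SD (ddof = 1).
* Study CSVs are written with a fixed float format; two runs with the same
  config and seed are byte-identical.  All randomness (phantom organs,
  swarm) derives from named SeedSequence spawns of the global seed.

## Problem sizes

All automated experiments run the 2D path on grids of roughly 150²–160²
cells at 5 mm spacing (solver validation uses up to 140×400 at 2.5 mm),
twelve channels, 15 periods per solve; the 3D solver is exercised on small
uniform blocks.  These sizes were chosen so a full study sweep (sites ×
3 GTV sizes × 7 schemes) completes on a single CPU core in minutes while
keeping ≥ 20 cells per wavelength in every tissue at 100 MHz.

## Known limitations

* 2D transverse geometry is the default study path; axial field structure
  (ring-to-ring interference of a 3D applicator) only enters through the
  coarse 3D solver, which is not the tested study path.
* The uniform grid ignores the conformal/non-uniform gridding of
  commercial solvers; reduced and detailed models share one grid by
  design so metric differences isolate segmentation effects.
* Absolute THQ/|dTHQ| magnitudes on synthetic phantoms are not clinical
  predictions; only the relative ordering of segmentation schemes and the
  directional effects (more high-conductivity volume mis-assigned → larger
  error) are meaningful.
* Thermal simulation (T50, CEM43) is out of scope; the 5 % THQ ↔ 0.2 °C
  link is a cited constant.
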