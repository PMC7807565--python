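# Methods

This note documents the model, its parameters, the numerical choices and
the limitations of `ovhqa`.  It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The prediction model assumes that, within one treatment protocol, the mean
OAR dose at a given distance from the PTV is approximately patient
independent.  Three steps:

1. **Per-patient dose–distance curve.**  Every OAR voxel yields a point
   (signed PTV distance, planned dose, voxel volume).  Distances are
   voxel-center-to-voxel-center Euclidean distances with anisotropic
   spacing, computed by two exact distance transforms
   (`scipy.ndimage.distance_transform_edt`), negative inside the PTV.  The
   sign convention makes the in-PTV dose plateau representable, and OAR
   volume overlapping the PTV is kept (with negative distances) rather than
   cropped.  Points are aggregated into half-open distance bins
   `[edge, edge + w)` starting at the minimum observed distance; the bin
   value is the *volume-weighted* mean dose (so mixed-resolution cohorts
   aggregate consistently), and empty bins are undefined (NaN), never
   zero-filled.
2. **Population model.**  Curves are linearly interpolated — never
   extrapolated — onto a common distance grid stepped at the training bin
   width and spanning the union of occupied ranges.  At each grid point the
   25th/50th/75th percentiles over the contributing patients are taken
   (linear interpolation between order statistics, `np.percentile`
   default).  Grid points where fewer than a configurable fraction of
   patients (default 50%, and never fewer than 2) contribute are undefined.
   The 25th percentile is the *low-dose* bound: lower dose at fixed
   distance means better sparing, so the band spans the best 25% to 75% of
   training plans.
3. **Prediction.**  Each OAR voxel's distance is looked up in a percentile
   curve by linear interpolation; the volume-weighted inverse cumulative
   histogram of the resulting voxel doses is the predicted DVH.  The band
   is *fully correlated*: the p25/p75 DVHs push every voxel through the
   respective curve wholesale.  Prediction reads only contours — deleting
   the dose array changes no output bit (verified by test).

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| distance bin width `w` | 2.5 | mm | typical dose-grid resolution; finer bins trade noise for resolution |
| dose bin (DVH axis) | 0.1 | Gy | DVH metrics are exact to half this bin |
| percentile levels | 25/50/75 | — | the prediction band definition |
| min. defined fraction | 0.5 | — | distance-grid points supported by fewer patients are undefined |
| prescription | 50 / 25 | Gy / fractions | protocol emulated by the generator |
| margins GTV→CTV / CTV→PTV | 5 / 10 | mm | protocol margins, applied as exact metric dilations |
| fall-off scale τ | Uniform(25, 35) | mm | per-patient dose fall-off steepness |
| dose noise σ | 0.5 | Gy | additive Gaussian voxel noise |
| phantom grid | 2.5 mm, 80×120×120 | — | desk-scale pelvic volume (20 × 30 × 30 cm) |

Out-of-range distances at prediction time are clamped to the nearest
defined model grid point (far voxels receive the lowest defined dose); the
clamped volume fraction is recorded on the result and logged as a warning
so users can judge model applicability.

## The synthetic cohort: what it emulates, what it does not

The generator reproduces the *premise* of the method: one PTV built from a
GTV ellipsoid by exact metric margins, a bladder (anterior–inferior, with
its own larger size variability emulating different filling levels) and a
large superior bowel bag, and a dose that is the prescription inside the
PTV and decays exponentially with PTV distance outside.  Patient-to-patient
variability covers target position/size, OAR position/size, fall-off scale
τ and monitor units; per-patient parameters come from sub-streams keyed by
(seed, patient index), so extending a cohort never re-randomizes earlier
patients, and every drawn parameter is returned in a log for
parameter-recovery checks.

Because the generated dose is a *deterministic function of PTV distance*,
the anatomy-aware prediction absorbs geometry changes almost exactly; the
residual prediction error is dominated by the mismatch between each
patient's τ and the training cohort's median τ.  Two consequences, both
measured by the acceptance checks and worth stating plainly:

* The mean Δ(mean dose) of a validation cohort fluctuates around zero with
  a standard deviation of roughly 0.5 Gy across seed choices, driven by the
  sampling error of the 22-patient training median of τ (standard error
  ≈ 1.1 mm, at a sensitivity of ≈ 0.45 Gy/mm).  The per-patient SD sits
  near 1.3–1.7 Gy given the 2.9 mm SD of τ.
* Increasing *geometric* heterogeneity (e.g. doubling the bladder-size
  variance) barely changes the prediction error, because size changes only
  re-weight a fixed error-versus-distance profile.  In clinical data the
  bladder's poorer predictability arises from dose deviating from the
  population distance relation for atypical anatomy (planning priorities,
  filling state) — a mechanism a distance-only dose model cannot express.
  Passing tests on these phantoms therefore validate the machinery, not
  the clinical heterogeneity response.

## Numerical choices

* **Rasterization** uses voxel-center containment with the standard
  half-open even-odd ray cast (bottom/left edges inside, top/right edges
  outside), which is deterministic for centers exactly on an edge and never
  double-counts shared edges; multiple polygons on a slice XOR-combine, so
  holes work.  It is verified against a naive scalar point-in-polygon
  oracle.
* **Distance maps** are exact (verified against O(N²) all-pairs
  computation, sign and magnitude, on random masks).
* **Dmean** from a cumulative DVH is the trapezoidal integral over dose,
  which equals the volume-weighted voxel mean to within half a dose bin
  (attained exactly when doses sit on bin boundaries).  **Dmax** is the
  exact per-voxel maximum, carried on the curve object; no near-maximum
  surrogate (e.g. D2%) is used.  **Vx** thresholds are linearly
  interpolated on the dose axis; thresholds beyond the axis return 0 with
  a warning.
* **Volume-delta normalization**: for absolute-volume metrics the
  normalized delta is delta / patient's OAR volume × 100 (%); for
  relative-volume metrics the delta is already a percent of the structure
  volume and passes through unchanged.
* **Degenerate statistics** are flagged, not silently filled: a constant
  paired-difference vector yields p = NaN with a `degenerate` flag;
  cohorts with n < 2 per metric omit SD and p with a warning.
* **Resampling** is trilinear for dose and nearest-neighbour for masks;
  target voxels outside the source extent are zeroed and counted.
* **Model files** are schema-versioned JSON; truncated files and version
  mismatches raise explicit errors, and a reloaded model predicts
  bit-identically.

## Design choices that were genuinely open

* Whether the population curve is count- or volume-weighted: volume
  weighting was chosen for cross-resolution consistency.
* Whether out-of-range voxels are clamped or discarded at prediction:
  clamping was chosen so the predicted DVH always integrates the full OAR
  volume, with the clamped fraction surfaced for scrutiny.
* The bladder "V35%" is read as the relative volume receiving ≥ 35 Gy; both
  the threshold and the absolute/relative flavour are configuration, so the
  alternative reading (35% of prescription = 17.5 Gy) is a config change.
* Distances are computed on the voxel grid, not on a sub-voxel surface
  mesh; contour planes must be axial and coplanar.

## Problem sizes

The reference experiments run 22 training and 30 validation phantoms on the
2.5 mm 80×120×120 grid; unit tests use a 3 mm 40×64×64 phantom and
hand-built small grids.  These sizes were chosen so the entire suite and
the acceptance script each complete in minutes on a single CPU while
keeping ≥ 10⁵ OAR voxels per phantom.

## Known limitations

* No realistic VMAT dose calculation or optimizer emulation; the
  exponential fall-off is one pluggable monotone family.
* No covariate-adjusted or machine-learning extension of the percentile
  model; no biological indices (EUD, NTCP) or conformity metrics.
* DICOM support covers RTSTRUCT/RTDOSE with axial closed planar contours
  and uniform frame spacing; RTPLAN is not parsed beyond user-supplied MU
  metadata; no PACS/DIMSE networking.
* The placeholder goal sheet ships with non-clinical values and must be
  replaced before any clinical use.
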