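# Methods

## Problem and model

In diffuse large B-cell lymphoma (DLBCL), baseline whole-body PET/CT carries
prognostic information beyond clinical scores: total metabolic tumor volume
(TMTV) and lesion-dissemination distances (Dmax, Dbulk) predict
progression-free and overall survival. This package implements a family of
dissemination biomarkers that use the **spleen centroid as an anatomical
reference point**, motivated by the spleen's role in the lymphatic system:

* For a patient with lesions *B₁…B_N* (centroids in physical mm) and spleen
  centroid *A*, the reference distances are *dᵢ = ‖Bᵢ − A‖*.
* **SpreadSpleen** = population standard deviation of the *dᵢ*
  (σ = √(Σ(dᵢ−μ)²/N), divide-by-N), in cm.
* **Dspleen** = max *dᵢ*, in cm.
* **sDspleen** = Dspleen (in m) / BSA (m²), where BSA is the Mosteller body
  surface area √(weight kg × height cm)/60; reported ×100 in m⁻¹.
* **TMTV** = Σ lesion volumes (cm³); **Dmax** = max pairwise centroid
  distance; **Dbulk** = max distance from the largest-volume lesion's
  centroid to any other centroid.

All features are defined for every patient, including single-lesion patients
(Spread = 0, Dmax = Dbulk = 0 by convention, Dspleen = that lesion's
distance). Centroids are unweighted means of member-voxel physical
coordinates; no PET-uptake weighting is applied. Geometry is carried in mm
through the NIfTI affine (voxel-center convention); distances are reported
in cm and volumes in cm³, with conversions centralized in `_units.py`.

A note on the BSA formula: some renderings of the Mosteller rule drop the
radical. The implemented form is √(w·h)/60; at the reference inputs
(72 kg, 168 cm) this gives 1.833 m², which is the only form consistent with
the ×100 sDspleen magnitudes the biomarker is reported in.

## Segmentation quality control

Automatically segmented spleen masks are screened for two failure modes:
more than one connected component, and falling (partly) outside the
whole-body field of view. Multi-component masks are auto-corrected by
keeping the largest component; the correction is idempotent and never
increases volume. Out-of-FOV and empty masks cannot be repaired
geometrically and are flagged `needs_manual_review`; the pipeline excludes
such patients explicitly (an exclusion list is part of the run provenance),
and a user-supplied replacement mask is the manual-correction pathway.

Two thresholds are this package's own choices where the screen is otherwise
under-specified: connectivity defaults to 26 (the most permissive 3D
adjacency, avoiding spurious multi-component warnings from thin necks), and
containment requires ≥ 95% of spleen voxels inside the FOV region (the FOV
defaults to the full image grid when no body mask is supplied). Both are
configurable and recorded in the QC report.

## Survival protocol

For each endpoint (PFS, OS — months assumed as the time unit):

* **Cutoffs**: sample median by default; a censoring-weighted Youden-index
  optimizer over observed thresholds of the time-dependent ROC at a
  configurable horizon; or a fixed published value (220 cm³ for TMTV).
  Tie-break is the lowest qualifying threshold.
* **Kaplan–Meier / log-rank**: product-limit curves per risk group and the
  k-group log-rank test (lifelines). Two-group splits dichotomize one
  biomarker; three-group stratification combines TMTV (cutoff 220 cm³) with
  a spleen feature (median cutoff): both-low / one-high / both-high.
* **Cox models**: maximum partial likelihood with Efron tie handling,
  solved by a vectorized Newton–Raphson iteration implemented in
  `_coxph.py`. The solver's score and information are assembled with suffix
  cumulative sums, making a fit cheap enough to sit inside bootstrap loops
  with thousands of refits; the test suite pins it against lifelines'
  `CoxPHFitter` to ~1e-6 on random data, including heavily tied times.
  Covariates enter on their natural scale (with the ×100 convention for
  sDspleen); dichotomized coding is available through the cutoff rules.
  Non-convergence (e.g. separation on small resamples) is reported on the
  result, never silent; bootstrap loops record such resamples as undefined
  rather than propagating garbage estimates.
* **Uncertainty**: patient-level bootstrap (resampling rows with
  replacement, default 5,000 draws in the library API; analysis runs
  document the count used) with empirical 2.5/97.5 percentile intervals,
  fully seeded. The reported interval is widened, if necessary, to bracket
  the full-sample point estimate.
* **Discrimination**: Harrell's C of the model's linear predictor
  (lifelines; ties ½, censoring-respecting comparability), orientation
  fixed so reported C ≥ 0.5 with the flip recorded; censoring-weighted
  cumulative/dynamic AUC at the horizon (scikit-survival's estimator,
  labeled as such). The default horizon is 48 months; the single-number AUC
  per feature/endpoint is this cumulative/dynamic AUC at that horizon.
* **Concordance gain**: to test whether adding a biomarker to a baseline
  Cox model improves discrimination, both models are fitted once on the
  full table and the paired patient-level bootstrap of
  C(extended) − C(base) on identical resamples yields the CI and a
  two-sided proportion-based p-value. Refitting both models inside every
  resample was deliberately not adopted: with fixed linear predictors the
  statistic isolates the discrimination difference, and the design keeps
  repeated-cohort calibration experiments tractable. With one added degree
  of freedom at the cohort sizes used, the optimism of the full-sample fit
  is negligible (the null calibration test verifies ≥ 90% non-rejection).
* **Subgroups**: any boolean filter (e.g. no splenic invasion) re-runs the
  configured analysis, guarded against under-powered subsets
  (≥ 20 patients, ≥ 5 events) and recorded in the report.
* No multiple-testing correction is applied; p-values are reported raw.

## Synthetic cohorts

No public imaging cohort exists for this problem, so validation rests on
phantoms with known ground truth. The generator emulates:

* a whole-body ellipsoid (half-axes 145 × 105 × 235 mm on a 96³ grid at
  4 × 4 × 6 mm) with an ellipsoidal spleen (40 × 35 × 45 mm → 264 cm³,
  matching a typical adult spleen) at a fixed left-upper-quadrant offset,
  jittered per patient (SD 6 mm);
* 1 + Poisson(7) spherical lesions placed uniformly in the body, radii
  log-normal (median 15 mm, σ_log = 0.6, clipped to 6–40 mm), redrawn when
  two spheres would intersect so lesion identity is unambiguous in voxel
  space; with probability 0.2 the first lesion is seeded inside the spleen
  (splenic invasion; the realized invasion fraction is ≈ 1/3 of patients);
* weight ~ N(72, 13²) kg and height ~ N(168, 10²) cm, truncated positive;
* survival from a Weibull proportional-hazards model,
  h(t) = h₀(t)·exp(Σβⱼzⱼ) with shape 1.2 and scale 120 months, by
  closed-form inversion of the cumulative hazard; βⱼ are per within-cohort
  SD of the listed features (defaults: 0.4 for TMTV, 0.5 for Dspleen);
  independent exponential censoring at 0.008/month; OS adds an exponential
  progression-to-death lag (mean 30 months) so PFS ≤ OS by construction.

These defaults were chosen once as the generator's study conditions: they
put the observed 4-year PFS event share near 26%, the TMTV median near
300 cm³, SpreadSpleen near 6 cm, and — because lesion positions and volumes
are drawn independently and the max-distance statistic saturates with
lesion count — keep |ρ(TMTV, Dspleen-family)| typically below 0.25,
reproducing the empirical decoupling of burden and dissemination.
`decorrelate_check` reports what a given cohort achieved.

Two paths share one geometry model. The default fast path computes features
directly from the analytic sphere centroids and volumes — exact, and cheap
enough for the hundreds of simulated cohorts the calibration experiments
need. The rendered path digitizes every shape into NIfTI label volumes by
voxel-center inclusion and runs the image-based extraction end to end;
round-trip agreement between the two (centroidal distances within one voxel
diagonal, volumes within a few percent at these voxel sizes) is itself a
tested invariant. The splenic-invasion flag differs slightly in kind
between paths (centroid-inside-ellipsoid vs voxel overlap) and can disagree
for grazing contact.

What the phantoms do **not** emulate: PET intensity and texture, scanner
noise and reconstruction effects, irregular lesion shapes, and expert
delineation variability. Passing tests therefore demonstrate correctness of
the geometry, the QC logic, and the statistical machinery under known
ground truth — not clinical performance on real cohorts.

## Problem sizes and numerical choices

Calibration experiments use scaled-down designs chosen as reasonable
Monte-Carlo sizes: log-hazard-ratio recovery over 50 cohorts of n = 300
with 500 bootstrap resamples; null calibration of the log-rank test over
500 cohorts of n = 120; concordance-gain null and power over 50 + 50
cohorts of n = 300 with 400 paired resamples. The acceptance script runs a
single cohort of n = 282 with 1,000 resamples plus a 20-patient rendered
imaging run.

Numerical details: the Newton iteration stops at a step max-norm below
1e-9 (50 iterations cap); exp overflow in the partial likelihood is avoided
by shifting the linear predictor by its maximum (the likelihood is
shift-invariant); Dbulk ties (equal volumes) break deterministically to the
lowest lesion id; nearest-neighbor resampling between grids is opt-in only,
since silent resampling can move centroids; label volumes reject
non-integer data beyond 1e-6 of an integer. Grid alignment tolerance is
1e-3 mm on affine entries.

## Known limitations

* The Youden cutoff uses a simple IPCW weighting of cases at the horizon;
  near-zero censoring-survival weights are clipped at 1e-12.
* The concordance-gain p-value is a bootstrap proportion, not an exact
  test; its resolution is 2/n_resamples.
* The rendered path digitizes spheres/ellipsoids only; no partial-volume
  modeling.
* Liver/bladder reference organs reuse the spleen pipeline unchanged (an
  organ tag on the feature vector); no organ-specific QC is implemented.
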