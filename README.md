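# splenomark

Spleen-referenced tumor dissemination biomarkers for lymphoma PET/CT, with
the full survival-analysis protocol needed to evaluate them.

## What this is for

In diffuse large B-cell lymphoma (DLBCL), how far the disease has spread at
baseline carries prognostic information beyond tumor burden alone. This
package computes, from co-registered lesion and organ label volumes
(NIfTI), a family of geometric biomarkers that describe tumor location
relative to the **spleen centroid** — an anatomically meaningful reference
in a lymphatic malignancy — and runs the statistical protocol that
evaluates them against progression-free and overall survival. It is aimed
at imaging researchers who already have lesion delineations (expert or
automatic) and an organ segmentation, and want reproducible biomarker
tables and survival reports.

For a patient with lesion centroids $B_1,\dots,B_N$ and spleen centroid
$A$, with $d_i = \lVert B_i - A\rVert$:

| Feature | Definition | Units |
|---|---|---|
| TMTV | $\sum_i V_i$ | cm³ |
| SpreadSpleen | $\sigma = \sqrt{\tfrac1N\sum_i (d_i-\mu)^2}$ | cm |
| Dspleen | $\max_i d_i$ | cm |
| sDspleen | Dspleen / BSA, BSA $=\sqrt{wh}/60$ (Mosteller) | m⁻¹, reported ×100 |
| Dmax | $\max_{i,j}\lVert B_i-B_j\rVert$ | cm |
| Dbulk | max distance from the largest lesion's centroid | cm |

All six are defined for every patient, including single-lesion patients.
The survival side covers median/Youden/fixed cutoffs, Kaplan–Meier risk
groups with log-rank tests, Cox proportional-hazards models (Efron ties,
in-package Newton solver), Harrell's C and time-dependent AUC, patient-level
bootstrap confidence intervals, a paired-bootstrap concordance-gain test,
and subgroup re-runs (e.g. patients without splenic invasion). A
synthetic phantom-cohort generator with known geometric and survival ground
truth makes every stage testable without any data download. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from splenomark.features import Lesion, LesionSet, ReferencePoint, features_from_lesions
from splenomark.synthetic_cohort import CohortSpec, simulate_cohort
from splenomark.survival import analyze_endpoint

# two lesions, spleen centroid at the origin
ls = LesionSet("PT01", [Lesion(1, (30.0, 0.0, 0.0), 10.0),   # mm, cm3
                        Lesion(2, (0.0, 40.0, 0.0), 2.0)])
spleen = ReferencePoint("spleen", (0.0, 0.0, 0.0))
fv = features_from_lesions("PT01", ls, spleen, weight_kg=72, height_cm=168)

# a synthetic 282-patient cohort with known survival ground truth
cohort = simulate_cohort(CohortSpec(n_patients=282, seed=1))
rep = analyze_endpoint(cohort.table, "pfs", ["tmtv_cm3", "d_cm"],
                       n_bootstrap=1000, seed=2, km_feature="d_cm")
```

which prints (via the fields of `fv` and `rep`):

```
TMTV          12.00 cm3
SpreadSpleen   0.50 cm
Dspleen        4.00 cm
sDspleen x100  2.18 1/m
Dmax           5.00 cm   Dbulk   5.00 cm

PFS Cox (TMTV + Dspleen), n=282, events=140
HR per cm Dspleen: 1.108 (95% CI 1.058-1.176)
C-index: 0.655 (0.606-0.704)
log-rank p (median Dspleen split): 0.0007
t-AUC at 48 mo: 0.660
```

The two lesions sit 30 mm and 40 mm from the spleen, so the mean distance
is 35 mm with population SD 5 mm (SpreadSpleen 0.5 cm) and the farthest is
4 cm (Dspleen); they are 50 mm apart (3-4-5 triangle), giving Dmax = Dbulk
= 5 cm. On the simulated cohort — whose generator ties the hazard to TMTV
and Dspleen — the fitted Cox model recovers a positive Dspleen effect
(HR > 1 per cm) with a concordance near 0.65, and the median Dspleen split
separates two risk groups (log-rank p < 0.001).

Image-based workflows go through `volume_io.read_label_volume`,
`spleen_qc.qc_spleen` and `features.extract_features`, or the CLI:

```sh
splenomark simulate --n-patients 20 --seed 1 --out cohort/
splenomark run-all --config run_config.json
```

`run-all` executes QC → feature extraction → survival and writes
`qc_report.csv`, `features.csv`, `survival_report.json` and a provenance
file with config hash and artifact checksums; identical configs reproduce
the artifacts byte for byte.

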