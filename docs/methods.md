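# Methods

This note documents the models, conventions and numerical choices behind
`petresponse`, in the order the pipeline applies them.

## Scope and assumptions

The package implements the *quantitative* half of a longitudinal FDG
PET/CT monitoring workflow for metastatic breast cancer: everything that
happens after a lesion segmentation exists. Producing the segmentation
(networks, registration) is upstream and out of scope; segmentations,
organ masks and acquisition metadata are inputs. Consequences:

* All volumes of one patient must share a lattice (shape, spacing,
  origin). Inter-volume operations fail loudly on mismatch; no implicit
  registration or resampling is performed. `resample_to_grid` is
  provided for the one standard preprocessing step (CT onto the PET
  grid) and is explicit, trilinear, and fill-value aware.
* Voxel indices are 0-based; a voxel's world position is
  `origin + index * spacing` (mm). All geometry — in particular the
  SULpeak sphere — is computed in world millimetres, so anisotropic
  voxels are handled for free.
* PET value semantics (`activity_Bq_per_mL`, `suv_bw`, `sul`, …) are
  declared by the caller, never inferred from headers. The injected
  activity is required to be decay-corrected to scan start; no decay
  arithmetic is done anywhere.

## SUV normalisations

`SUV_bw = C · W_g / A` with `C` the activity concentration (Bq/mL),
`W_g` body weight in grams and `A` the injected activity (Bq).
`SUL` replaces weight by the Janmahasatian lean body mass:

    LBM_female = 9270·W / (8780 + 244·BMI)
    LBM_male   = 9270·W / (6680 + 216·BMI),   BMI = W / H²

These coefficients are the single source of lean mass in the package.
The regression is empirical: below BMI ≈ 12 the male branch extrapolates
above total weight; we implement the formula faithfully and do not
clamp.

Clipping SUV to [0, 5] is provided solely to emulate
segmentation-network input preprocessing (SUV 2.5 being the classical
malignancy threshold, the clip window centres the contrast around it).
Biomarkers are always computed on unclipped images — a clip at 5 would
destroy SULpeak and TLG of hot lesions.

## Imaging biomarkers

* **SULpeak** — a sphere of diameter 1.2 cm is centred on *every*
  segmented voxel; the reported value is the maximum sphere-mean SUL.
  The sphere contains all image voxels whose centres lie within the
  radius (inclusive `≤` comparison), not only segmented ones, so the
  peak need not sit on the hottest voxel. Discretisation: a voxel
  belongs to the sphere iff its centre is within 6.0 mm of the
  candidate centre's world position; on a 2 mm isotropic grid this
  yields 123 voxels. Spheres reaching beyond the image border are
  truncated to existing voxels (and counted in the log). One value is
  reported per acquisition, pooled over all lesions. Ties on the
  maximum resolve to the first candidate in scan order. The
  implementation is verified against an exhaustive brute-force search
  to exact floating-point equality.
* **MTV / TLG** — lesions are connected components of the segmentation
  (26-connectivity by default; configurable to 6 or 18). Label order is
  deterministic: components are numbered by their first voxel in a
  lexicographic (z, y, x) scan. Per lesion, `MTV = n_voxels ·
  voxel_volume` (mL) and `TLG = MTV · SUVmean`, with SUVmean taken on
  the SUV_bw image; the per-acquisition TLG is the sum over lesions.
* **PBI / PLI** — whole-body bone (liver) tumour-burden indices:
  `100 · V_lesions-in-organ / V_organ`. A lesion is attributed to an
  organ when strictly more than half of its voxels lie inside the organ
  mask, bone taking precedence over liver if both exceed the threshold
  (overlapping organ masks are allowed but logged). An attributed
  lesion contributes its *full* volume to the numerator, keeping the
  index in lesion-volume units; counting only the intra-mask fraction
  is a documented alternative a caller can build from
  `assign_organ` + `lesion_stats`. An empty organ mask makes the index
  undefined and raises.

An empty segmentation yields zero MTV/TLG/PBI/PLI and an
undefined-flagged SULpeak; downstream, the response stage reads an
undefined SULpeak as 0 (no measurable disease), which makes complete
response a −100 % change.

## Segmentation evaluation

Two Dice variants: the mean of per-acquisition Dice (sensitive to
errors on acquisitions with few lesions) and a global Dice pooling all
acquisitions' voxel counts (sensitive to errors on large lesions).
Both-empty pairs are defined as Dice 1 (flagged degenerate).

Detection uses the 50 %-overlap component rule: a ground-truth
component is detected (TP) iff at least half its voxels are covered by
the pooled prediction, otherwise FN; a predicted component is FP iff
*less than* half its voxels overlap the pooled ground truth. The
asymmetry at exactly 50 % (TP yes, FP no) is intentional and tested.
The FP denominator is the predicted component's own volume — the
reading consistent with the bone-lesion detection scheme this rule
descends from; the threshold is configurable.

## Response assessment

For each biomarker, `Δ(%) = 100 · (FU − BL) / BL`. Zero-baseline
policy: `0/0 → 0` (flagged `zero_baseline`), `x/0 → +∞` sentinel
(flagged `new_disease`, always a non-responder call). PERCIST expert
categories binarise as CR/PR → responder, SD/PD → non-responder.

ROC orientation: response is a *decrease*, responders are the positive
class, and a subject is called responder when `Δ ≤ t`. Candidate
thresholds are exactly the observed Δ values (plus a −∞ sentinel); no
midpoint interpolation. The AUC is the trapezoidal area, which equals
the Mann–Whitney concordance estimator. The operating point maximises
Youden's `J = sensitivity + specificity − 1`, ties broken toward the
most negative Δ (the most conservative responder call). Sensitivity
and specificity are reported with responder as the positive class.

Paired AUCs are compared with DeLong's placement-value test (structural
components, two-sided normal approximation); comparing a biomarker with
itself gives z = 0, p = 1 by construction. Agreement between two
measurement routes uses Lin's concordance correlation coefficient with
population (biased) moments as in Lin's original estimator (sample
moments available via a flag), Spearman's rank correlation and the
Wilcoxon signed-rank test. All tests are two-sided; the reporting layer
applies the significance level (default 0.001) — p-values themselves
are never thresholded inside the statistics.

## Synthetic phantom cohort

The generator emulates the statistical structure of a baseline/follow-up
monitoring cohort, not anatomy. Defaults (one set of study conditions,
fixed once):

| parameter | default | rationale |
|---|---|---|
| grid | 96×96×192 @ 3 mm iso | whole-body PET scale at typical voxel size |
| background / liver SUV | 1.0 / 2.0 | typical soft-tissue and liver uptake |
| lesion count | Poisson(8), min 1, cap 15 | multi-metastatic disease |
| lesion diameter | 8–40 mm | sub-centimetre to bulky lesions |
| lesion SUV | 3–15 | above the 2.5 malignancy threshold |
| PSF FWHM | 6 mm | clinical PET resolution |
| noise sd | 0.05 SUV | visually plausible background noise |
| responder SUV/volume factors | U(0.3,0.7) / U(0.3,0.8) | PR-range decreases |
| non-responder factors | U(0.95,1.4) / U(1.0,1.3) | stable to progressive |
| responder fraction | 0.5 | balanced classes for ROC testing |

Geometry is stylised: an elliptic-cylinder body, an ellipsoidal liver,
a spine cylinder plus a transverse pelvic tube for bone. Lesions are
spheres placed at voxel centres, fully inside their target region
(placement uses a per-region Euclidean distance transform), mutually
separated by at least 2.5 voxel pitches so connected-component labelling
can never merge them. The first lesions are forced into bone and liver
so the organ indices are exercised by construction.

Follow-ups scale each lesion's amplitude and volume by per-patient
response factors. A lesion whose scaled amplitude falls below local
background + 0.3 SUV is considered resolved and leaves the follow-up
mask. The PERCIST label derives from the planted factors — CR when all
lesions resolved (probability 0.15 among responders), PR otherwise for
responders; PD for SUV factor ≥ 1.3 or a planted new lesion (the new
lesion case clamps the factor to ≥ 1 so progression never shrinks the
remaining disease), SD otherwise — so the planted responder flag always
agrees with the binarised category.

Ground-truth masks are the *pre-PSF* lesion supports, mimicking experts
outlining lesions rather than their blur tails; this keeps detection
metrics meaningfully below 1 under degradation. Truth biomarkers are
bookkept from the piecewise-constant pre-PSF model by voxel counting,
so on noiseless, PSF-free phantoms the measured panel on the truth mask
reproduces them to floating-point accuracy — this identity is an
acceptance test.

Phantoms are generated directly in SUV_bw space with nominal metadata
(female cohort, weight ~N(70, 12) kg clipped to [45, 110], height
~N(1.65, 0.07) m, 4 MBq/kg injections), avoiding any pretence of
scanner calibration; the activity↔SUV conversions are exercised by
dedicated unit tests instead. What the phantom does **not** model —
reconstruction artefacts, respiratory motion, physiological uptake
(brain, bladder, myocardium), lesion texture, inter-scanner effects —
bounds what passing tests say about real data: they validate the
measurement and statistics pipeline, not segmentation difficulty on
clinical images.

## Pipeline and reproducibility

`run_study` streams patients (memory-flat in cohort size), computes
panels on the reference masks and on an automatic route (classical
SUV ≥ 2.5 threshold segmentation with ≥ 2-voxel components), and emits
five tables: `panels`, `deltas`, `response`, `concordance`,
`segmentation`. All randomness descends from a single master seed via
spawned substreams; identical config + seed yields byte-identical CSVs
(the output directory is excluded from the config hash for that
reason). Cohort class counts are planted exactly:
`round(responder_fraction · n)` responders, assignment by seeded
permutation.

Problem sizes used by the shipped validation: the exhaustive SULpeak
and detection oracles run on ≤ 20³ grids (50 seeds each); truth
recovery uses 20 noiseless full-size phantoms; planted-effect recovery
uses 20 cohorts of 60 patients at full grid size; the acceptance script
reports one 60-patient study.

## Known limitations

* PERCIST is binarised; the five-category classification is not
  automated (deliberately out of scope).
* SULpeak is pooled per acquisition; per-lesion peaks are available but
  are a convenience output only.
* The Δ statistic is undefined for a truly new-lesion baseline of zero;
  the +∞ sentinel policy is a convention, tested but not the only
  defensible one.
* NIfTI is the only supported volume format; DICOM ingestion (and its
  decay-correction chains) is a non-goal.
* Organ attribution is whole-lesion majority voting; a lesion straddling
  an organ boundary contributes all of its volume or none of it.
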