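# Methods

## Model and procedure

The pipeline operationalizes reference-tissue-normalized threshold
segmentation for FLT PET/CT of lymphoma. Its premise is that liver and
bone-marrow FLT uptake are stable across treatment stages on cohort
average, so either can normalize a lesion threshold. The quantities, in
order of computation:

**Reference measures.** For patient *j* at stage *k* ∈ {baseline, iPET,
fPET}, the liver measure is the mean SUV and within-VOI voxel SD in a
sphere (29 mm default; 41/48 mm presets) at a configured center; the
marrow measure is the same over the T12 vertebral body (L3 and
T10–T11–T12 presets), delineated on CT as the voxels inside a search box
with HU in [150, 1500], reduced to the largest 26-connected component
with interior holes filled, then carried to the PET grid.

**Stability.** Per-tissue one-way fixed-effects ANOVA of per-patient
mean SUV across stages (`scipy.stats.f_oneway`), plus per-patient
percent relative change vs baseline, RC = 100·(SUV_k − SUV_base)/SUV_base.

**Normal ranges and eligibility.** The normal uptake range of a tissue
is the pooled mean ± 1 sample SD (divisor N−1) over *all* patient-stage
measurements. A scan's reference is the liver when hepatic uptake lies
within the liver range (bounds inclusive), else the marrow when within
its range, else the scan is excluded. For each tissue separately, the
eligible patient set at a stage comprises scans whose uptake of *that*
tissue is in range — which is why lesion counts can differ between the
liver and marrow rows of the detection table.

**Thresholds.** RT(stage, tissue) is the unweighted mean over eligible
lesions of SUVmin/SUVref; the criterion-n absolute threshold is
RT·(SUVref + n·SDref), n = 0, 1, 2; the reformulated threshold is
R̃T = (RT/N_pat)·Σ_j (SUVref_j + n·SDref_j)/SUVref_j. The defining
identity holds in the ratio domain: the per-patient absolute threshold
divided by the patient's reference uptake averages exactly to R̃T (and
R̃T = RT exactly at n = 0; R̃T is strictly increasing in n whenever any
within-VOI SD is positive).

**Segmentation.** Foreground = voxels with SUV *strictly greater than*
the absolute threshold, minus the physiological-uptake exclusion mask
(liver, vertebrae, planted hot regions); components by 26-connectivity
(6 available), labelled deterministically (descending size, ties by
lexicographically smallest voxel). A reported lesion is detected when
≥ 1 of its mask voxels is foreground; no minimum component size is
applied by default (single-voxel detections count). MTV is foreground
voxel count × voxel volume, in ml.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| liver VOI | 29 mm sphere | mm | closest to the PERCIST convention; 41/48 mm presets for sensitivity |
| marrow VOI | T12 | — | single vertebra suffices given low inter-vertebra variability; L3, T10–T12 presets |
| vertebra HU range | [150, 1500] | HU | brackets trabecular-to-cortical bone against soft tissue (~40 HU); configurable |
| within-VOI SD divisor | N (population) | — | the VOI is the complete measured voxel set and SD serves as a spread scale in criteria 2/3; `ddof` switch provided |
| cohort SD divisor | N−1 (sample) | — | inter-patient spread is a sample estimate |
| selected criterion | baseline 3, iPET 1, fPET 2 | — | shipped default selection per stage; an input, not computed (the selection step is qualitative expert review, out of scope) |
| threshold inequality | strict (>) | — | boundary-equal voxels are background |
| connectivity | 26 | — | standard for 3D PET lesion labelling; 6 via config |

## The phantom generator

`fltseg.synthetic` emulates the study conditions, not scanner physics.
Defaults: 16 patients × 3 stages on a 64×64×80 grid at 2.5 mm isotropic
spacing (a fixed 160×160×200 mm body layout). Per patient, true liver
and marrow uptake are drawn from Gaussians truncated at 0.5 SUV
(5.1 ± 1.4 and 7.8 ± 2.7 SUV), constant across stages by default
(per-stage drift multipliers available to probe the stability analysis).
The CT holds soft tissue at 40 HU, an air border at −1000 HU and four
vertebral bodies at 300 HU; the PET holds a 1.0 SUV background, liver
and marrow plateaus at the true uptakes, a 12 SUV physiological hot
sphere, multiplicative Gaussian voxel noise with coefficient of
variation `within_voi_cv` (default 0.05), and 1–3 ellipsoidal lesions
per scan placed in disjoint cells of a lesion zone.

Lesion uptake falls linearly from a central plateau (2× the minimum by
default) to the designed minimum at the rim; the rasterized profile is
affinely rescaled so the noiseless voxel minimum equals the designed
minimum exactly, and noisy lesion voxels are floored at it. Without the
floor, the minimum of ~10²–10³ noisy voxels would be biased low by more
than the noise CV itself, decoupling the planted fraction from what the
threshold estimator measures; flooring keeps SUVmin the controlled
quantity. Designed minima are `lesion_min_fraction` × the patient's true
uptake of `lesion_reference` (liver by default; per-stage fractions
default to 0.50/0.35/0.27, mirroring the decreasing tendency of relative
thresholds along treatment). A volume-free summary generator draws the
same per-patient truths (same seed, same values) and emits measures and
lesion records directly, for fast statistical tests; its measured means
carry a small sampling jitter (cv/√500 of truth) and its SDs are
cv × truth.

What the phantoms do *not* model: partial-volume blur and contrast
recovery, reconstruction artefacts, attenuation, respiratory motion,
heterogeneous lesion texture, anatomy beyond boxes/spheres/ellipsoids.
Passing tests therefore demonstrate the *procedure* — its algebraic
identities, eligibility mechanics, monotonicity and parameter
recovery — not clinical segmentation accuracy; on real data,
partial-volume effects make small-lesion minima systematically lower
than planted-phantom ones.

## Numerical choices

- Sphere/ellipsoid membership by voxel center; inclusion uses ≤ on the
  radius. Deterministic, grid-convergent (sphere volume error < 2% at
  1 mm spacing for a 29 mm sphere).
- All randomness flows from a single integer seed through named
  `numpy.random.SeedSequence` substreams (patient parameters, voxel
  noise, summary jitter), so volumetric and summary cohorts share
  per-patient truths and reruns are byte-identical.
- Displayed percentages round half-up to integers; all computation uses
  full precision.
- Degenerate ANOVA input (all groups constant and equal) returns F = 0,
  p = 1 rather than 0/0.
- Truncated-Gaussian draws use rejection sampling; with SD = 0 the mean
  is returned directly.
- Resampling: CT→PET (never the reverse), trilinear for HU,
  nearest-neighbour for masks; SUV statistics are always computed on
  native PET voxels. Oblique NIfTI affines are rejected.
- SUV conversion assumes decay-corrected activity upstream (scanner
  reconstruction); the library neither applies nor removes decay
  correction.

## Problem sizes

Default test and validation sizes were chosen so the whole suite and the
acceptance script each complete in well under a minute on one CPU:
16-patient volumetric cohorts for end-to-end runs, 30-patient /
~120-lesion summary cohorts for threshold recovery, 2000 replicates for
ANOVA calibration, and 100 random instances per brute-force oracle
comparison. All scale linearly if enlarged.

## Known limitations

- Liver sphere placement is an explicit coordinate (from the phantom
  ground truth or a manifest); automatic segment-VIII localization is
  out of scope.
- Vertebra delineation takes the whole vertebral body; an interior-only
  (cortex-eroded) variant would need a morphological erosion option.
- Criterion selection per stage is configuration, not computation.
- Matching segmented components to reported lesions uses ≥ 1 voxel of
  mask overlap; merged components detecting several lesions are counted
  per lesion, not diagnosed.
- Cohort-specific published threshold values cannot be reproduced
  without the original scans; the package reproduces the estimator and
  its identities on synthetic cohorts.
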