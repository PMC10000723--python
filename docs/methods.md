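# Methods

This note documents the models, conventions and numerical choices behind
`spinefs`: what the phantom simulator emulates, how the GAN and its joint
SSIM + adversarial loss are defined, how the preprocessing chain and the
agreement statistics are specified, and where genuinely open design choices
were resolved.

## The synthesis problem

Sagittal spine MRI protocols routinely acquire T1-weighted and
non-fat-saturated T2-weighted series; the fat-saturated T2-weighted (T2-w fs)
series that makes edema, inflammation and fluid collections conspicuous is
frequently missing. The signal content of a T2-w fs image is, to first
order, a function of the two acquired contrasts — fat is bright on T1-w and
non-fs T2-w but suppressed with fat saturation, while fluid is bright on
both T2-w contrasts — so a conditional image-to-image model can synthesize
the missing series from a co-registered (T1-w, non-fs T2-w) pair. The
package trains such a model slice-wise on sagittal slices and reassembles
synthetic volumes, then quantifies the diagnostic value of the synthetic
series through inter-rater agreement statistics on a six-pathology grading
schema.

## Spine phantom simulator

Patient images cannot ship with the package, so `spinefs.phantom` generates
paired multi-contrast phantoms that reproduce the *statistical* structure
the generator must learn, deliberately not anatomy or scanner physics.

**Geometry.** A label volume of shape `(slices, rows, cols)` (default
`10 x 64 x 64` at `3 x 1 x 1` mm) contains a column of `n_vertebrae`
(default 5, a typical field of interest) rectangular vertebral bodies with
interposed discs, a posterior CSF-cord-CSF band, a paravertebral fat layer
and muscle elsewhere. Per-slice one-voxel boundary jitter and cord-free
lateral slices give the third dimension mild variability.

**Signal model.** Each tissue is a three-compartment mixture
`(fat_fraction, fluid_fraction, base_signal)` with `fat + fluid <= 1`, and
each contrast is a fixed linear weighting `w_fat * fat + w_fluid * fluid +
w_base * base`:

| contrast | w_fat | w_fluid | w_base |
|----------|-------|---------|--------|
| T1-w     | 1.0   | 0.15    | 1.0    |
| T2-w     | 0.9   | 1.0     | 1.0    |
| T2-w fs  | 0.0   | 1.0     | 1.0    |

The zero fat weight on T2-w fs *is* the fat-suppression contract: pure-fat
voxels collapse to their base signal, pure-fluid voxels are identical on
both T2-w contrasts. The linear model was chosen for analytic testability,
not biophysical fidelity; it makes every contract (suppression ratios,
edema conspicuity) checkable in closed form. Additive Gaussian noise
(default sd 0.02 on a roughly unit-amplitude signal) is seeded and
deterministic.

**Pathologies and grading.** Lesions are ellipsoids clipped to their parent
structure, with the ellipsoid scale bisected so the *measured* covered
fraction of the vertebral body matches the requested extent. Edema-carrying
lesions exchange fat signal for fluid signal (`fluid += 0.6 (1 - fluid)`,
`fat *= 0.3`), making them bright on both T2-w contrasts and iso-to-dark on
T1-w; chronic fractures convert toward fat, hematomas toward T1-bright
fat-like signal. Ground-truth grades follow the six-pathology schema: bone
marrow abnormalities 0-4 (absent / focal / one-third / two-thirds / whole
body), spondylodiscitis expansion 0-3 by thirds, Modic type 1 changes and
cord lesions binary, fractures 0/1 (acute, edema present)/2 (chronic), and
paravertebral abnormalities by subtype 1-3. The schema names thirds but not
a focal cutoff; the focal/one-third boundary is set at 10 % of the body
volume as this package's choice, with the third boundaries at 1/3 and 2/3.

**Simulated readers.** `simulate_readers` misgrades each item to an adjacent
legal grade with a configurable per-pathology probability — adjacent-grade
confusion being the plausible clinical error mode. Defaults encode the
premise under study: reading without a fat-saturated series is harder for
fluid-sensitive pathologies (misgrade probability 0.30 for bone marrow,
spondylodiscitis, Modic and cord lesions; 0.15 otherwise), while the
synthetic protocol reads at 0.10 throughout. Simulated cohorts default to
101 datasets and two readers with per-pathology prevalences of roughly
60/5/28/21/15/25 per 101 for the six kinds, mirroring a mixed clinical
spine population. These defaults are fixed study conditions, not tuning
knobs.

What the phantoms do *not* contain — curved spines, scanner- and
field-strength-dependent contrast, bias fields, metal artifacts, through-
plane anisotropy effects, reader-experience structure — bounds what passing
tests show: they demonstrate that the implementation learns and measures
what it claims on data with the stated statistical structure, not clinical
performance.

## Preprocessing

1. **Resampling** to 1 x 1 mm in-plane by linear interpolation. Grid
   convention: voxel centres with a half-open world extent, so a plane of
   `H` voxels at spacing `s` becomes `round(H s)` voxels — stated because
   output shapes differ across conventions.
2. **Rigid co-registration**, T2-w fixed. In-plane rigid (rotation about
   the slice centre plus 2-D translation in mm) estimated on z-normalized
   mean sagittal slices by mean-squared-difference: a coarse grid search
   (3-degree / 3-mm steps on 2x-decimated images) seeds a bounded Powell
   refinement. The registrar is implemented in-repo so the pipeline has no
   binary dependency; parameter-recovery tests against known phantom
   misalignments hold it to 0.5 degrees / 0.5 mm. Z-normalization makes the
   MSD criterion usable across contrasts of the linear phantom family;
   genuinely multi-modal data would want a mutual-information criterion
   (out of scope).
3. **Capping and scaling.** Intensities are clipped to the per-volume 1st
   and 99th percentiles (linear-interpolation order-statistic convention)
   and affinely mapped so p1 -> -1 and p99 -> +1. Per-volume (not per-slice,
   not per-cohort) percentiles are an assumption, stated. Degenerate volumes
   (p1 == p99) map to zeros with a flagged record rather than dividing by
   zero. The `NormalizationRecord` is persisted so synthesis output can be
   mapped back to display range.
4. **Slice extraction** into `(N, 2, H, W)` inputs and `(N, 1, H, W)`
   targets; targets may be absent for synthesis-only use.

## GAN

**Generator.** U-Net encoder-decoder, skip connections at every level,
2-channel input, 1-channel tanh output in [-1, 1]. Desk-scale default:
depth 3, base 16 channels (sized so a 25-epoch run on 200 slices completes
in minutes on one CPU core; both are configurable). Dropout (rate 0.5)
in the deepest decoder blocks follows the pix2pix convention of noise
injection; at inference dropout is off by default so synthesis is
deterministic, with stochastic synthesis exposed as an opt-in flag. Inputs
whose sides are not divisible by `2^depth` are reflect-padded and cropped
back.

**Discriminator.** Patch-based: three stride-2 4x4 convolution blocks over
the channel concatenation of the conditioning pair and the candidate slice,
then a 3x3 convolution to a grid of per-patch logits (8 x 8 for 64 x 64
input; receptive field 38 px). Conditioning-by-concatenation is the
standard realization of a conditional discriminator.

**Joint loss.** The generator minimizes

    L_G = (1 - SSIM(real, synthetic)) + lambda * BCE(1, D(synthetic)),

with lambda = 50; the discriminator minimizes
`BCE(1, D(real)) + BCE(0, D(synthetic))`, patch-averaged. SSIM rather than
an L1/L2 term tolerates residual misregistration because it compares local
statistics, not pixels. SSIM uses an 11 x 11 uniform window,
`C1 = (0.01 L)^2`, `C2 = (0.03 L)^2` with dynamic range `L = 2` for the
[-1, 1] scale, sample-covariance normalization `n/(n-1)`, and averages over
fully valid windows only — these choices make the implementation agree with
`skimage.metrics.structural_similarity(win_size=11, data_range=2)` to float
precision, which the tests exploit as an independent oracle.

**Training.** Discriminator and generator update in turns on each
mini-batch (batch 8), Adam with learning rate 2e-4 and betas (0.5, 0.999),
25 epochs, slices visited in a freshly drawn random order each epoch.
Augmentation applies flips and rotations (up to 10 degrees) identically to
inputs and target, and Gaussian smoothing / noise to the input channels
only — intensity corruption of the regression target would bias the
reconstruction term. The per-epoch history logs the (1 - SSIM) and
lambda-BCE components separately; the reported generator loss is defined as
their sum, so the decomposition is exact by construction. All randomness
(initialization, shuffling, dropout, augmentation) derives from one seed
and the arithmetic is single-threaded numpy, so training reproduces
bit-exactly.

**Numerical engine.** The networks and the differentiable SSIM run on a
small in-repo reverse-mode autodiff tape over numpy (`spinefs.nn`):
convolution as one BLAS contraction per kernel offset, the SSIM window as
an O(HW) integral-image box filter, BCE in a logit-stable softplus form.
Two engine-level properties matter beyond gradients (which are tested
against central differences at ~1e-9 relative error): backward closures
never capture their own output node and the topological sort is iterative,
so computation graphs are freed by reference counting immediately — a
cyclic graph would otherwise accumulate multi-gigabyte garbage between
collector runs during long trainings.

## Volume synthesis

Inference passes every sagittal slice through the generator and restacks in
order; outputs stay in [-1, 1] with the T2-w normalization record attached
for display-range inversion, and the output NIfTI copies the T2-w geometry.
When a real T2-w fs is supplied, per-slice SSIM and its arithmetic mean form
the quality surface. At the desk-scale study conditions (20 training
phantoms = 200 slices, 25 epochs, seed-fixed) held-out volume-mean SSIM
lands around 0.9 with fat-dominant voxels darker on the synthetic image
than on the input T2-w essentially everywhere; the 0.80 / 90 % thresholds
asserted by the tests are this package's desk-scale bar, not a clinical
claim.

## Agreement statistics

* **Cohen's kappa**, unweighted — the grades are treated as categorical,
  ordinal weighting deliberately excluded. CI as kappa +/- 1.96 SE with the
  Fleiss-Cohen-Everitt large-sample variance (matching `statsmodels`);
  kappa is flagged undefined when chance agreement is 1. Both readers'
  gradings are pooled as independent rows per pathology before kappa; the
  pooling rule is this package's documented choice.
* **Accuracy** is the fraction of exact grade matches against ground truth.
* **Wilcoxon signed-rank** on the six pathology-wise kappa pairs: zero
  differences discarded, mid-ranks with tie correction, asymptotic
  two-sided normal p without continuity correction. On the published kappa
  pairs this convention yields p = 0.043 where exact enumeration gives
  0.0625; the package implements the former (the convention of the common
  statistics packages) and ships the exact enumerator as a test oracle
  documenting the gap.
* **McNemar** on paired correctness indicators: exact two-sided binomial p
  while discordant counts stay below 25, continuity-corrected chi-square
  above; no discordance returns p = 1, flagged.
* Significance is read at 0.05 without multiple-testing correction,
  matching the evaluation design this layer models.

Undefined (NaN) kappas — possible for rare pathologies in small simulated
cohorts — are excluded from the mean-kappa aggregate and the Wilcoxon
comparison rather than poisoning them.

## Pipeline and reproducibility

`run_end_to_end` chains simulate -> train -> synthesize -> simulate readers
-> evaluate. One global seed fans out to per-stage seeds by stable hashing
(`stage_seed`), so stages are decoupled; every stage directory carries the
hash of the configuration that produced it and is skipped on rerun when the
hash matches. Reruns with an unchanged seed reproduce the report JSON
byte-identically.

`scripts/acceptance.py` recomputes the headline quantities from scratch at
the desk-scale problem sizes stated above (six kappa pairs; 200 training
slices / 25 epochs; 20 registration seeds; a 101-dataset simulated reader
study) — sizes chosen as the package's desk-scale study conditions.

## Known limitations

* The phantom's linear signal model makes the (T1, T2) -> T2fs mapping
  nearly deterministic per voxel; real tissue, coil shading and pathology
  heterogeneity are far harder, so phantom SSIM levels say nothing about
  clinical image quality.
* The registrar is in-plane rigid only; through-plane motion and deformable
  misalignment are out of scope.
* Simulated readers have no inter-reader correlation structure beyond the
  shared ground truth and error rates; per-reader kappa breakdowns are out
  of scope.
* SSIM is computed slice-wise in 2-D; no 3-D window is attempted.
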