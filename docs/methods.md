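# Methods

## Scope and data model

The package segments a single thin intraventricular structure (the lateral
ventricle choroid plexus) from one anatomical MRI contrast at a time, and
evaluates the result the way a segmentation-validation study would: overlap
and surface metrics against ground truth per subject, method-agreement
statistics across measurement routes, and a cross-sectional volumetry model
against age.

Volumes are 3-D scalar grids with a NIfTI voxel-to-world affine (RAS+ mm,
0-based indexing); masks are strictly binary on the same grids. Spatial
transforms map native world coordinates to template world coordinates as a
4×4 affine with optional dense displacement fields supplied externally. The
package deliberately does not estimate registrations: it applies, inverts
and resamples under given transforms (linear interpolation for intensities,
nearest neighbour for labels). Mask volume is voxel count × voxel volume,
reported in cm³.

## Synthetic phantoms

Because no patient images ship with the package, a phantom module generates
study cohorts whose geometry and statistics exercise every pipeline stage:

* A head ellipsoid of uniform "parenchyma" intensity provides a total
  intracranial volume (TIV) covariate.
* Two ventricle ellipsoids are built mirror-symmetrically about the
  mid-grid sagittal plane (the right compartment is the voxel mirror of the
  left one, so compartment symmetry is exact by construction). Ventricular
  volume grows 20% per decade of age by default, as an atrophy proxy.
* The target is one jittered cubic-spline curve per atrium, rasterized by
  taking the *n* ventricle-interior voxels nearest the curve, where *n* is
  the voxel count of the requested volume. Rank-based rasterization
  calibrates the realized volume to the request exactly (up to candidate
  supply) while the shape remains a thin curved tube — deliberately the
  geometry that stresses Dice and Hausdorff metrics. Erosion of the
  ventricle by one voxel keeps the target strictly interior.
* Expected target volume is `base · (1+g)^((age−20)/10) + male_offset`,
  defaults 1.5 cm³ at age 20 (female), g = 0.15/decade, +0.4 cm³ for males —
  the planted signal that the lifespan statistics later recover. Age and sex
  modulate only geometry, never intensity. An optional per-subject Gaussian
  volume scatter (`volume_scatter_cm3`, default 0 so the volume-calibration
  invariant holds exactly) emulates inter-individual variability; lifespan
  cohorts enable it so regression residuals — and hence McFadden's R² — are
  on a realistic scale rather than degenerate near-zero variances. Head size
  is jittered a few percent per subject to give the cohort a varying TIV
  covariate.
* Intensities are unitless in [0,1] from a per-sequence lookup
  (T1-like: parenchyma 0.70 / CSF 0.20 / plexus 0.55; T2-like:
  0.40 / 0.90 / 0.55; FLAIR-like: 0.45 / 0.15 / 0.60), plus additive
  Gaussian noise (default sd 0.05). The lookups reproduce the clinical
  contrast ordering — near-isointense to parenchyma on T1-like images,
  intermediate on T2-like, bright against suppressed CSF on FLAIR-like.

What the phantoms do **not** model: MR physics (bias fields, Rician noise,
partial voluming, motion), anatomical variability beyond ellipsoids and
spline jitter, and non-identity registration errors (transforms default to
identity; synthetic affines can be attached to exercise resampling).
Passing tests therefore demonstrate that the pipeline machinery — sampling,
training, reassembly, inversion, metrics, statistics — is correct and that
the network can learn a contrast-plus-context segmentation task; they do not
certify accuracy on clinical MRI.

## Atlas and patches

The probabilistic atlas is the voxelwise mean of training masks; support is
taken as probability > 0 (no thresholding). The crop box is the support
bounding box expanded by an 8-voxel margin and padded to multiples of 8 so
that three 2× poolings reproduce shapes exactly; a minimum-size option
guarantees the box can host at least one inference window. Patch centres
are drawn uniformly over support with replacement (probability-weighted
sampling would concentrate on the structure core; the uniform reading keeps
rare peripheral anatomy in view and is the minimal interpretation of
"random atlas voxels"). Windows that would cross a grid face are shifted
inward rather than zero-padded, so every patch carries real image content.
Mirror augmentation is deterministic doubling — each patch plus its
mid-sagittal reflection — which reproduces the 41 × 50 → 4100 sample
arithmetic exactly; a stochastic flip probability is available but not the
default.

## Network and training

The model is a 3-level 3-D U-Net: encoder blocks of two (3³ conv, batch
norm, ReLU) layers with filters 64→128→256 (configurable base), 2³
max-pooling after each block; decoder blocks mirror this with 2³-stride
transposed convolutions and skip concatenations (the cited architecture
concatenates encoder features; a flag disables it); head is a 1³ convolution
with tanh, so scores live in (−1, 1). Scores map to probabilities by
p = (y+1)/2, the unique monotone affine map of (−1,1) onto (0,1); the
binarization threshold y > 0 is its p = 0.5 point.

Training minimises the two-class generalized Dice loss with inverse squared
class-volume weights, guarded by ε = 10⁻⁸ when a class is absent, under
Adam at learning rate 10⁻⁴ (batch 4, up to 200 epochs, early stopping on
validation loss with patience 20 — batch/epoch policy is a package choice,
stated in `TrainConfig`). The loss gradient is computed in closed form and
backpropagation is hand-derived per layer; gradients are verified against
finite differences in the test suite. Training is bit-deterministic given
the seed on a fixed BLAS.

The engine is pure NumPy in channels-last layout. Convolutions are lowered
to one GEMM per kernel tap with the product scattered into a shifted
accumulator; this keeps the working set cache-resident and is what makes
CPU training of scaled-down models practical (≈1 s per forward+backward on
a 4×32³ batch with 8 base filters).

## Inference

Full-subject segmentation resamples the native image to the template grid,
tiles the atlas crop box with a sliding window of stride = half the patch
edge (full coverage, windows shifted inward at faces), averages overlapping
scores (order-independent and smooth, the standard choice for sliding-window
inference), binarizes at y > 0, decrops, and inverse-resamples the mask to
native space with nearest neighbour. Voxels no window reaches keep the
background score −1.

## Metrics

* **Dice**: 2|A∩B|/(|A|+|B|); two empty masks score 1 (documented
  convention).
* **HD95**: surface voxels are foreground voxels with a background
  face-neighbour (grid exterior counts as background); directed distances
  are Euclidean in world mm honouring anisotropic spacing; the statistic is
  the max of the two directed 95th percentiles (linear-interpolated), the
  common medical-imaging dialect. A pooled-percentile variant sits behind a
  flag. The KD-tree implementation is tested to 10⁻⁹ against an all-pairs
  oracle.
* **Voxelwise AUC**: Mann–Whitney rank formulation, so binary predictions
  score (sensitivity+specificity)/2 and ties count ½. Evaluated over the
  atlas crop box rather than the whole head, so true negatives outside the
  region of interest do not inflate the statistic.
* **ICC**: default ICC(2,1) — two-way random effects, absolute agreement,
  single measure — computed from the ANOVA mean squares; methods are the
  "raters", and absolute agreement is what volume interchangeability
  requires. ICC(3,1) is available; the form is recorded in output.
* **Bland–Altman**: bias = mean difference; limits = bias ± 1.96 × sample
  sd (ddof 1).

## Cohort statistics

GLMs are Gaussian with identity link (the responses — volumes and metric
values — are continuous), fitted by maximum likelihood via statsmodels, with
Wald p-values. McFadden's pseudo-R² = 1 − ll_model/ll_null uses the Gaussian
log-likelihoods of the fitted and intercept-only models. The lifespan model
is volume ~ age + sex + TIV; the age effect is summarised as
percent-per-decade = 100 · (10 · β_age) / mean(volume) — slope per decade
relative to the cohort mean, the definition recorded in output. Single-sex
cohorts drop the sex covariate with a warning.

Method comparisons pair by subject id and use the two-tailed Wilcoxon
signed-rank test (zeros dropped; exact null for n ≤ 25 without ties, normal
approximation with tie correction otherwise; an unpaired rank-sum variant is
provided). All p-values emitted within one analysis batch are adjusted by
Benjamini–Hochberg step-up with monotonicity enforcement.

## Cross-validation protocol

Five folds; with n subjects, each fold holds n/5 for test and n/5 for
validation, training on the rest (30/10/10 at n = 50). Every subject is a
test case exactly once, and one seed yields the same fold plan for every
sequence so per-sequence models share participant groups. Each fold's atlas
is built from that fold's training masks only — anything else would leak
test ground truth into the crop region and sampling density — and a
leakage guard fails the run if test ids reach training inputs. An
atlas-threshold baseline (probability > 0.5 mask) is scored on the same
test subjects as the reference any learned model must beat.

## Scaled problem sizes

The shipped tests and the acceptance script use scaled-down study
conditions chosen once: 20 phantoms on 64³ grids (ventricle base 5 cm³,
target base 1 cm³), 8 base filters, 32³ patches, 6 patches per subject
before mirroring, 3 epochs at learning rate 2×10⁻³, batch 4 — the smallest
configuration we found that trains to clearly useful accuracy on one CPU in
minutes. The lifespan cohort uses 98 subjects on 48³ grids with
proportionally smaller anatomy (target base 0.45 cm³, male offset
0.15 cm³) and the planted 15%/decade growth. The full-size defaults
(64 filters, 64³ patches, 41 patches/subject, lr 10⁻⁴) remain the package
defaults and run through the identical code path.

## Numerical conventions and edge cases

Degenerate inputs raise typed errors rather than returning silent values:
empty masks for HD95, single-class regions for AUC, zero total variance for
ICC, all-zero paired differences for Wilcoxon, rank-deficient designs for
the GLM. Ties in patch-overlap averaging cannot occur (arithmetic mean);
ties in AUC are handled by midranks; percentile interpolation is linear.
The generalized Dice loss is exactly 0 for a perfect ±1 prediction and
exactly 1 for a fully inverted one.

## Known limitations

* Phantom realism, as above; in particular FreeSurfer-style external masks
  are consumed from files and no real external segmentations ship with the
  package, so `compare_methods` is exercised with synthetic degradations.
* The NumPy engine targets correctness and CPU practicality at small scale,
  not GPU-class throughput; full-size (64-filter, 64³-patch) training is
  supported but slow.
* Clinical-scale accuracy figures (Dice ≈ 0.7 is typical for this structure
  on patient MRI) require real cohorts and cannot be established from
  phantoms; phantom accuracies are much higher because the synthetic task
  is easier.
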