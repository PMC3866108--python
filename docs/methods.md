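# Methods

## Overview

`neoseg` segments co-registered T1- and T2-weighted neonatal brain volumes
into eight tissue classes plus background by supervised per-voxel
classification. The pipeline is: multiplicative shading (bias-field)
correction → average-brain (atlas) construction from the cohort's T2
volumes → per-voxel feature extraction (two intensities + three
atlas-space coordinates) → feature standardization → kNN posterior
estimation with optional class-imbalance weighting → probabilistic maps,
majority-class labels, volumetry and overlap metrics.

The model assumptions are those of intensity-plus-location voxel
classification: tissue classes occupy approximately consistent positions
across subjects once mapped into a common (atlas) frame, and class
intensity distributions are stable within a cohort after bias correction
and standardization. No shape prior, no spatial regularization and no
partial-volume mixture model is used; each voxel is classified
independently.

## Coordinate conventions

Voxel indices are 0-based; world coordinates are RAS+ millimetres through
the NIfTI affine. All spatial features are world coordinates, never voxel
indices, so subjects with different grids are directly comparable.
Transforms are 4×4 homogeneous matrices mapping fixed-image world
coordinates to moving-image world coordinates (the resampling direction);
`invert` is the matrix inverse.

## Shading correction

Inhomogeneity is modelled as `I_obs = I_true · exp(P(x))` with `P` a 3-D
polynomial of total degree `order` (default 2, valid 1–4) over coordinates
normalized to the mask bounding box. `P` is estimated by minimizing the
within-class variance of the corrected log-intensity: a deterministic 1-D
Gaussian-mixture E-step (8 components — one per expected tissue mode —
quantile-initialized, soft responsibilities) gives each voxel an expected
class mean; the polynomial is the closed-form least-squares fit to the
residual; the two steps alternate. This sits in the same
information-minimization family as histogram-entropy shading correction but
has a convex inner step, making it deterministic and fast.

Two numerical choices matter:

- **Bounded alternation (default 5 rounds).** The field estimate converges
  to the true shading within a few rounds; run to stationarity, the
  polynomial starts absorbing genuine anatomical contrast (smooth tissue
  layouts project onto low-order polynomials). Bounding the iteration count
  is the same safeguard N4-style correctors use. On phantoms with ±8%
  order-2 fields, recovery correlation between estimated and true log-field
  is 0.95–0.98 for SNR 10–40 and degrades gracefully below SNR 8.
- **Mean preservation.** The corrected image is rescaled so the mean
  intensity over the mask is unchanged; the scale is folded into the
  field's constant term.

Degenerate inputs: an empty mask is an error; a constant image returns the
identity field. Soft responsibilities (rather than hard nearest-centre
assignment) remove a spatially structured misassignment bias that
otherwise leaks anatomy into the field when noise overlaps tissue peaks.

## Registration and atlas

`register_affine` maximizes mutual information (Mattes, 32 histogram bins
by default) over three resolutions (subsampling factor 2 per level, 200
optimizer iterations per level, 5000 random metric samples per iteration,
fixed sampling seed), with a rigid stage for coarse alignment followed by a
full affine stage; SimpleITK provides the metric and optimizer. The
contract is on recovery accuracy, not optimizer internals: known ±3 mm
shifts are recovered within 0.05 mm and 5° rotations within 0.35° on
phantoms; self-registration returns near-identity.

The average brain is built by iterative registration and averaging of the
T2 volumes: iteration 0 is the plain voxelwise mean (so no individual
subject biases the reference), then each iteration registers every subject
to the current average, resamples and re-averages, stopping when the mean
absolute change of the average falls below `tol` (default 0.5% of the
intensity range) or after `max_iter` (default 5) iterations. The
convergence trace is recorded. Resampling maps target-grid voxels through
the transform and interpolates the moving image (linear for intensities
and probabilities — which keeps probabilities in [0,1] by convexity —
nearest for labels); out-of-field voxels are 0.

An elastic (B-spline) refinement stage is deliberately not implemented;
the registration options object is the hook for plugging an external
elastic backend with the same signature. Affine alignment suffices for the
phantom cohorts, whose inter-subject deformations are rigid.

## Features and training sampling

Each masked voxel yields (T1, T2, x_atlas, y_atlas, z_atlas); the spatial
columns are the voxel's world position pushed through the subject→atlas
transform. Training tables carry the reference label. Because a brain has
~10⁵–10⁶ voxels, training uses a per-subject simple random sample without
replacement of `fraction` (default 0.20) of each training image's voxels,
merged across subjects; sampling is per image, not from the pooled set, so
every subject contributes proportionally. A seed makes the sample
reproducible.

The brain mask is an input. When absent, a fallback is provided (union of
nonzero labels for training subjects; Otsu threshold + largest component +
closing for test subjects) — an artifact convention, clearly second-best to
a dedicated brain-extraction step. The background class is trained from a
thin (2-voxel) shell of non-brain voxels around the mask
(`train_background_shell`, on by default), so that posterior vectors cover
background as well as the eight tissues.

Feature scaling is to zero mean and unit variance with the *population*
standard deviation (divide by n), fit on the training rows only and applied
unchanged to test voxels; a zero-variance feature is an error.

## Classification

Posteriors are neighbour-count fractions m/k under Euclidean distance in
standardized feature space, k = 50 by default. Distance ties at the k-th
neighbour are resolved by admitting tied training rows in ascending row
order until exactly k — a deterministic rule an exhaustive
distance-matrix oracle reproduces exactly (the production path uses a
k-d tree and falls back to the exhaustive rule for the rare rows whose
k-th and (k+1)-th distances coincide).

The imbalance weighting assigns class i the weight
`w_i = (Num(C_i)/min_j Num(C_j))^(-1/exponent)`, exponent > 1, with Num
counting classes among the voxel's k nearest neighbours (default; a
`global` variant counts over the whole training set). Weighted posteriors
are renormalized to sum to 1 — renormalization cannot change the argmax,
and it restores the probability-map invariant. Weights are monotone in the
exponent and approach 1 as it grows; at exponent 75 the weighted and
unweighted majority segmentations agree on ≥ 99.9% of masked voxels in
leave-one-out runs.

Classification happens in native space by default: each native voxel's
features use its atlas-mapped coordinates, so no probability resampling is
needed and each voxel is classified exactly once. The alternative
`classify_space="atlas"` mode classifies the atlas grid and maps the
probability maps back through the inverse transform with linear
interpolation (renormalizing afterwards) — the flow a registration-centric
pipeline would use; both modes agree on > 98% of voxels on phantoms,
differing only at structure boundaries.

## Evaluation

Per class: TP/FP/FN/TN counted over a voxel universe (default: brain mask ∪
reference foreground; whole-image and bounding-box universes are options),
DSC = 2TP/(2TP+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP).
Conventions: DSC of two empty sets is 1.0, empty-vs-nonempty 0.0;
sensitivity/specificity with empty denominators are NaN. Volumes come in
two flavours — probabilistic (Σ posteriors × voxel volume) and binary
(majority-class voxel count × voxel volume, restricted to the mask) — and
paired volume comparisons use a paired-samples t-test with Bonferroni
correction at family level α = 0.01. The leave-one-out harness builds the
atlas once from all subjects (matching the method's construction from the
full cohort), then for each held-out subject trains on the remaining ones
and segments it; all seeds are logged and runs are bit-reproducible.

## Phantom generator

The phantom defines the study conditions for every test. A canonical
analytic model nests an extracerebral-CSF shell (outer 10% of the brain
ellipsoid radius), a CoGM ribbon (next 12%), a UWM core, paired CeGM
nuclei and ventricles, two thin MWM tracts (~0.5% of brain voxels —
mirroring the real rarity of myelinated white matter at term-equivalent
age, where it is ~1.7 cc of a ~480 cc brain), a brainstem stalk and a
cerebellar lobe; later structures overwrite earlier ones, so classes are
disjoint. Each subject views this model through a random rigid
perturbation (±2 mm, ±3° by default; the truth transform is returned),
draws class-conditional Gaussian intensities with T2-weighted neonatal
contrast (CSF/VENT brightest on T2, UWM brighter than grey matter, MWM
distinct mainly on T1; CSF-vs-VENT and CoGM-vs-CeGM are nearly
intensity-identical by design, so their separation must come from spatial
features), with class SD 4 and additive noise SD 6 (SNR ≈ 25; configurable
down to clinical levels), optional boundary blur (off by default —
intensities are piecewise constant), and per-channel multiplicative
order-2 bias fields with ±8% peak amplitude over the brain.

The default grid is 96×96×48 at (1, 1, 2) mm — the "fast" profile used
throughout the test suite and acceptance script (~120k brain voxels per
subject; a 7-subject leave-one-out runs in ~2 minutes on one CPU). A
"full" 192×192×96 profile at (0.5, 0.5, 1) mm exists for benchmarks.

What the phantoms do *not* emulate: cortical folding, partial-volume
mixing, motion artifacts, pathology, or within-class intensity gradients.
Passing tests therefore demonstrate the correctness of the pipeline's
machinery (registration, correction, classification, metrics) under known
truth — not clinical-grade accuracy on real neonatal scans, where overlap
scores will be substantially lower.

## Known limitations

- Affine registration of a blurred average against a nearly noise-free,
  symmetric phantom can drift in the scale/shear terms (the MI cost is
  flat along them); with realistic noise the affine stage is stable.
  `RegistrationOptions(rigid_only=True)` restricts to the rigid subset.
- The shading correction's bounded alternation slightly under-corrects at
  very low SNR, and re-running it on a corrected image at SNR ≈ 10 can
  re-estimate up to ~1% of residual structure (0.1–0.3% at the default
  noise level).
- The kNN model stores the full standardized training matrix; memory grows
  linearly with cohort size × sampling fraction.
- Background posteriors depend on the background-shell training convention;
  with it disabled, background probability arises only from mask handling.
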