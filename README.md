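# neoseg

Probabilistic segmentation of neonatal brain MRI into eight tissue classes
plus background, by supervised per-voxel k-nearest-neighbour classification.

Volumes of neonatal brain tissues at term-equivalent age are candidate
biomarkers for neurodevelopmental outcome, but manual slice-by-slice
annotation of a single scan takes on the order of 100 hours. `neoseg`
automates the task for co-registered T1- and T2-weighted scans. The eight
classes are cortical and central grey matter (CoGM, CeGM), unmyelinated and
myelinated white matter (UWM, MWM), cerebrospinal fluid in the extracerebral
space (CSF) and in the ventricles (VENT), brainstem (BS) and cerebellum (CB)
— notably separating ventricular from extracerebral CSF, both of independent
clinical interest in preterm infants.

## Method

Each brain voxel is described by five features: its T1 and T2 intensities
(after multiplicative bias-field correction) and its spatial position
(x, y, z in mm) in the coordinate system of an *average brain* built by
iteratively registering and averaging the cohort's T2 volumes. Features are
scaled to zero mean and unit variance on the training set. A kNN classifier
(k = 50, Euclidean distance) assigns each voxel a posterior probability per
class,

    P(class i | voxel) = (# class-i voxels among the k nearest training voxels) / k,

yielding a probabilistic segmentation per tissue; hard labels take the
majority (argmax) class. Because tissue classes are highly unbalanced (MWM
is ~1% of the brain), an optional local correction multiplies posteriors by

    w_i = (Num(C_i) / min_j Num(C_j)) ^ (-1/exponent),   exponent > 1,

where Num counts each class among the voxel's k neighbours — the rarest
class present gets weight 1 and large classes are discounted; as the
exponent grows the correction vanishes. Tissue volumes are computed both
probabilistically (sum of posteriors × voxel volume) and from the binary
segmentation, and compared against reference volumes with a paired t-test
with Bonferroni correction.

Because clinical scans cannot ship with the code, the package includes a
first-class phantom generator: multi-subject synthetic brains with the eight
disjoint tissue classes, class-specific T1/T2 intensity distributions,
additive noise, smooth multiplicative bias fields and per-subject rigid
perturbations — with all ground truths returned, so every stage (shading
correction, registration, atlas, classification, volumetry) is tested
against known answers.

## Worked example

Generate a 7-subject phantom cohort and run the leave-one-out evaluation
(each subject segmented by a model trained on the other six, 20% of brain
voxels sampled per training image):

```python
from neoseg import PhantomSpec, make_cohort
from neoseg.evaluate import LooOptions, leave_one_out

subjects = make_cohort(PhantomSpec(seed=42), 7)
res = leave_one_out(subjects, LooOptions(seed=0))
df = res.metrics_frame()
print(df.groupby("tissue")[["DSC", "sensitivity", "specificity"]].mean().round(3))
```

which prints

```
          DSC  sensitivity  specificity
tissue
BS      0.981        0.985        1.000
CB      0.968        0.974        0.998
CSF     1.000        1.000        1.000
CeGM    0.990        0.980        1.000
CoGM    0.992        0.992        0.998
MWM     1.000        1.000        1.000
UWM     0.999        0.999        1.000
VENT    1.000        1.000        1.000
```

Each row is the mean over the seven held-out subjects: DSC is the Dice
overlap 2TP/(2TP+FP+FN) between the predicted and true voxel sets of that
tissue, and sensitivity/specificity are the true-positive and true-negative
rates within the brain mask. On these well-separated phantoms the
classifier is near-perfect; the rare MWM class is carried by its distinct
T1 intensity and consistent location. `df` also carries per-class volumes
(probabilistic, binary and reference, in cc).

The same pipeline is scriptable from the shell:

```sh
neoseg phantom --n 7 --seed 42 --out cohort/
neoseg loo cohort/subject-* --out results/
```

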