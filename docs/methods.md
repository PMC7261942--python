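# Methods

`csvdseg` re-creates, as a reusable and testable framework, a four-network
"deep learning system" for segmenting the imaging signs of cerebral small
vessel disease (CSVD) on routine multi-sequence brain MRI: lacunes, white
matter hyperintensities (WMH), recent small subcortical infarcts, and
cerebral microbleeds. Real clinical cohorts of this kind are private, so the
package ships a phantom generator that reproduces the *statistical* structure
of such a cohort — lesion contrast directions per sequence, lesion diameter
ranges, voxel spacings, positive-case fractions — and every pipeline stage is
exercised end-to-end on phantoms.

## The segmentation model

One independent 2D U-Net is trained per lesion class. Volumes are processed
slice-by-slice and the per-slice masks are concatenated back into a volume;
slice spacing in this kind of acquisition is 6–8 mm, so 3D convolution has
little to gain and 2D slices match how such scans are read.

**Sequence routing.** Each network sees only the sequences on which its
pathology is conspicuous: subcortical infarct ← DWI b1000; WMH ← T2-FLAIR;
lacune ← T1 + T2-FLAIR (two channels; lacunes are CSF-like hypointense on T1
with FLAIR as supporting context); microbleed ← T2\*-GRE. Lacune routing is
switchable to T1-only via `SegmentorSpec.input_modalities`, since reasonable
readings of the labeling protocol support either.

**Architecture.** `depth` encoder levels of two 3×3 convolutions (leaky
ReLU) followed by 2×2 max-pooling, channel count `base · growth^level`
(growth 2 by default); a bottleneck block; a symmetric decoder of stride-2
2×2 transpose convolutions with skip connections and two more convolutions
per level; a final 1×1 convolution and sigmoid. Input edge must be divisible
by `2^depth`; output size equals input size.

The network engine is a compact numpy implementation (`csvdseg.nn`) with
explicit backward passes and Adam, validated by finite-difference gradient
checks in the test suite. Three details matter at small scale and are easy
to get wrong:

* **Leaky ReLU** (slope 0.01) instead of a plain rectifier: with sparse
  targets an entire tiny network can die in the first epochs and freeze.
* **Loss gradients flow through logits.** Binary cross-entropy's gradient
  w.r.t. probabilities, composed numerically with the sigmoid derivative,
  underflows to zero exactly when the network saturates; its closed-form
  logit gradient `(p − g)/N` does not.
* **Positive-balanced sampling.** Lesion-bearing slices are a small minority;
  each epoch keeps every slice and additionally repeats positive slices
  (up to 4×) so minibatches regularly carry signal. Without this the
  all-empty prediction is a strong attractor of the dice loss.

The train/validation split is patient-wise and stratified by class
positivity: both splits get at least one lesion-positive patient whenever
possible. An all-negative validation set would score the untrained empty
predictor at dice 1 (empty-vs-empty pairs count as 1) and freeze it as the
best checkpoint.

**Loss.** Default is the sum of per-slice soft dice and BCE. Pure soft dice
is available but at desk scale it collapses to the all-empty optimum; BCE
alone underweights small lesions. Threshold for binarization defaults to 0.5.

**Training accuracy and stopping.** "Accuracy" is the mean per-slice dice of
thresholded predictions, with empty-prediction/empty-reference slices
scoring 1. Pixel accuracy would sit at ≈1 under lesion sparsity and make any
high-percentage criterion meaningless. Training stops early when training
accuracy exceeds 0.98 **and** exceeds validation accuracy by more than 0.15
— i.e. when overfitting is detected. Because the rule fires on divergence,
the returned model is the best-validation checkpoint, not the final (by
construction overfit) weights. The divergence is signed (train − val), not
absolute.

**Scale-invariance augmentation.** In-plane pixel spacing in the emulated
cohort spans 0.36–1.44 mm. Rather than resampling to a uniform grid,
training batches are randomly zoomed by a factor in [0.75, 1.3] (then
cropped/padded back), so the networks tolerate the resolution spread.

## Preprocessing

Each slice is zero-padded to a centred square, resized to the network edge
(bilinear for intensities, nearest-neighbour for masks), and each volume is
intensity-normalized beforehand by white-matter histogram peak alignment:
the peak `p` of the WM lobe is detected and the volume is multiplied by
`reference / p`. The map is purely multiplicative (no offset), so the zero
background stays zero and the map is exactly invariant under global positive
rescaling of the input.

Peak detection without a tissue hint: histogram the above-background voxels
into 256 bins; on T1 and DWI (white matter bright) take the tallest bin in
the upper half of the intensity range; on FLAIR and T2\* take the mode of
the tissue lobe above Otsu's threshold, which separates it from the dark
background/CSF lobe. The argmax bin is refined by a parabolic fit over its
two neighbours, clamped to ±half a bin width — the raw argmax jitters by a
bin when the bin width is far below the noise scale. A `tissue_hint` mask
overrides detection entirely. Degenerate volumes (nothing above background,
or a non-positive peak) are rejected.

## Mask combination

WMH, lacune and infarct can look alike on FLAIR, so the raw masks are
reconciled by subtraction in a fixed order: infarct is removed from WMH,
then the **raw** lacune mask is removed from WMH, then infarct is removed
from lacune. Microbleeds are never modified. After combination the three
masks are pairwise disjoint at the voxel level; combination is idempotent
and never increases the positive voxel count. Whether WMH subtracts the raw
or the infarct-cleaned lacune mask is genuinely ambiguous; both satisfy the
invariants, the raw variant is the default and the other is a flag
(`subtract_raw_lacune=False`). Patients remain multi-label at the study
level: the summary lists every class with ≥1 voxel after combination.

## Evaluation

* **Dice** per patient, aggregated by unweighted arithmetic mean.
* **Patch-wise dice**: both masks are max-pooled in-plane onto square
  patches (edge ≈ √image-edge, default `round(sqrt(max(rows, cols)))`)
  before the dice — tolerant of few-pixel localization error. At patch edge
  1 it equals pixel dice exactly; at patch = image it degenerates to
  presence/absence agreement, the patient-level multi-label classification
  limit. For volumes, pooling is per-slice; slices are never pooled together.
* **Region-wise F1**: connected components (26-connectivity in 3D,
  8-connectivity in 2D; face-connectivity available) are the units. A
  reference lesion touched by any predicted voxel is a TP; untouched, an FN;
  a predicted component touching no reference lesion is an FP. By default
  matching is any-overlap with no one-to-one constraint (one predicted blob
  over two reference lesions = 2 TP, 0 FP); a greedy one-to-one variant is
  available. Both-empty patients score 1 with a flag and are included in
  means by default (the emulated evaluation cohort contains class-negative
  patients); a switch excludes them.
* **FROC**: lesion sensitivity and false-positive components per case over
  an ascending threshold sweep, using the same counting rules. Sensitivity
  is provably non-increasing in the threshold (masks are nested); the FP
  count typically decreases too but can momentarily rise when a component
  splits, so only sensitivity monotonicity is asserted.
* The "overall" row is reported two ways — mean of class means and pooled
  mean over all (patient, class) pairs — because either reading of an
  overall score is defensible.

## The phantom generator

The brain is a three-compartment ellipsoid: a grey-matter shell (outer 12%
of the radius), a white-matter interior, and two para-central CSF
ventricles. White matter is deliberately the dominant compartment — that is
the anatomical fact the WM-peak normalizer exploits. Base intensities per
compartment and sequence are arbitrary units in physiological *order* (e.g.
T1: WM 300 > GM 220 > CSF 60; FLAIR: GM 250 > WM 200 > CSF 40); only the
ordering is contractual.

Lesions are painted into white matter (falling back to anywhere inside the
brain when a large lesion cannot fit strictly inside WM on a small grid):

| class | diameter (max in-plane extent) | appearance |
|---|---|---|
| lacune | 3–15 mm | CSF-intensity on T1; isointense elsewhere |
| WMH | unconstrained (union of 2–4 overlapping blobs) | bright on FLAIR |
| infarct | ≤20 mm (2 mm floor so lesions are visible) | bright on DWI and FLAIR, dark on T1 |
| microbleed | 2–10 mm | dark on T2\* |

Directions marked "dark" render at 0.45× the WM base (the lacune on T1 at
the CSF intensity), "bright" at 1.6×. *Isointense entries paint nothing*:
an isointense lesion leaves the sequence's signal untouched, including any
earlier-rendered lesion it overlaps — overwriting at WM intensity would
punch unlearnable holes into overlapping WMH. Ground-truth masks of
different classes may overlap (exercising the combination stage), and each
lesion's diameter is guaranteed by constructing the footprint at an exact
integer pixel span. Gaussian noise (sd 4 by default, ≈2% of the WM level)
is added and intensities are clipped at zero. In-plane spacing is drawn
from 0.7–1.2 mm by default (within the emulated 0.36–1.44 mm envelope;
the defaults keep 20 mm lesions placeable on small grids), slice spacing
from 6–8 mm. Cohorts draw per-class positivity with the emulated cohort's
fractions (lacune/WMH 98.3%, infarct 85.15%, microbleed 41.78%); negative
patients have empty masks.

What the phantom does **not** model: anatomy beyond the ellipsoid, bias
fields, partial-volume effects, k-space artifacts, scanner-specific
intensity distributions, inter-sequence misregistration. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
networks can recover lesions under idealized contrast — not clinical-grade
performance on real scans.

## Problem sizes and numerical choices

The test suite and the acceptance script run the whole system at desk scale:
8-slice 64×64 phantoms, 24 training + 6 held-out patients (~192 training
slices per class), depth-2 U-Nets with 8 base channels, 14–24 epochs per
class (lacune discrimination against T1-dark infarcts, confluent WMH, and
small microbleeds need the longer budgets). Training phantoms are generated
all-positive so every class has enough lesion slices at this cohort size;
held-out phantoms keep the emulated positive fractions, as real evaluation
sets contain class-negative patients. Under these conditions each class
reaches held-out dice ≥ 0.6, with the focal classes typically ≥ 0.85. Dice of the empty-vs-empty pair is
defined as 1 throughout. Histogram peak detection uses 256 bins; soft dice
uses smoothing constant 1. All randomness flows from explicit integer seeds
(phantom config, segmentor spec); a fixed seed reproduces studies, training
histories and predictions bit-for-bit.

## Known limitations

* The numpy engine is CPU-bound and intentionally small; it is not a route
  to paper-scale training (1,500 patients, full-resolution slices).
* Training "accuracy" is a declared substitute for an undefined quantity;
  the stopping rule is faithful to its printed inequality but its behaviour
  depends on this metric choice.
* The phantom's intensity statistics are synthetic by construction; no
  claim transfers to scanner data without retraining and re-validation.
* Inputs are assumed co-registered; no registration is performed.
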