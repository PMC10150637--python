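# Methods

## Problem and model

`svnsfuse` addresses multiclass classification with two feature views of the
same instances — in the motivating application, fused deep-feature
descriptors of dermoscopy images from two CNN backbones — where single-view
classifiers disagree often enough that a principled fusion of their
decisions beats either alone.

The method trains two opposed one-vs-all (OvA) ensembles via
error-correcting output codes (ECOC):

* a **true** ensemble on view A, coding matrix +1 on the diagonal and −1
  elsewhere, so learner *k* fires on class *k*; decoded by **highest**
  similarity score;
* a **false** ensemble on view B with the negated coding matrix, so learner
  *k* fires on everything *except* class *k*; decoded by **lowest** score.

Each binary learner is a soft-margin SVM whose decision values are passed
through a Platt sigmoid, so per-class similarity scores live in [0, 1]. For
an instance with true score T_k and false score F_k on class k, the
single-valued neutrosophic (SVNS) characterization is

    I_k  = 1 − |T_k − F_k|                 (indeterminacy)
    CW_k = 1 if T_k > F_k else 0           (code-word bit)
    CR_k = (2 + T_k − I_k − F_k) / 3       (crisp value)

with 0 ≤ T + I + F ≤ 3 by construction. Resolution per instance:

1. exactly one bit set → that class (the ensembles agree);
2. no bit set → argmax of I (both ensembles reject everything; the least
   decisively rejected class wins);
3. two or more bits set → argmax of CR among bit-set classes.

Where CW_k = 1, CR_k = (1 + 2(T_k − F_k))/3 algebraically, so branch 3 is
an argmax of the score gap; where CW_k = 0 the formula cannot exceed 1/3,
which is why restricting the crisp search to bit-set classes is lossless.
Reported tables print the constant 1/3 in bit-clear cells; arithmetic is
unrounded internally, 6 decimals in text output.

Tie-breaking: T = F clears the bit (routing the instance toward the
indeterminacy branch), and argmax/argmin ties resolve to the lowest class
index. Both choices make classification deterministic and
permutation-equivariant under simultaneous reordering of the class order.

## ECOC ensembles

Coding matrices over {−1, 0, +1} (rows classes, columns learners): OvO with
n(n−1)/2 lexicographic pair columns, and the OvA true/false pair described
above. Per column, 0-coded classes are filtered out before fitting, never
zero-weighted. The binary learner defaults to a linear-kernel SVC with
C = 1 (kernel, C, and class weights configurable); calibration is a Platt
sigmoid fitted by 3-fold stratified, unshuffled cross-validation inside the
training set, so training is deterministic given a seed.

The OvA pair is the pipeline default because the neutrosophic stage
consumes exactly one score per (instance, class) from each polarity. OvO is
provided for completeness; its per-class score averages the calibrated
probabilities aligned with each column's code sign (p where the class is
coded +1, 1 − p where −1). This keeps OvO scores in [0, 1] and on the same
scale as OvA scores, at the cost of diverging from classical loss-weighted
hinge decoding; since OvO does not feed the neutrosophic stage, simplicity
and a single code path won.

## Feature fusion

Activation stacks from different network depths are fused by resampling
every stack to the minimum spatial size among the inputs (the later, more
abstract maps are the smallest, so earlier maps are downsampled to them)
and concatenating along channels, preserving input order. Fusion is applied
at two levels — fuse(a, b) then fuse(result, c) — which equals flat
three-way fusion whenever the intermediate minimum coincides with the
global one.

The bilinear resampler uses half-pixel sample centers (align-corners-false):
output pixel i maps to source coordinate (i + 0.5)·scale − 0.5, clamped at
the borders. Consequences relied on by tests: resampling to the source size
is an exact identity, a 2×2 block averages to its mean at 1×1, and affine
channels are reproduced exactly at interior sample centers. The
implementation is a short closed-form gather; scikit-image's order-1
`resize` shares the convention and acts as an independent cross-check.

Fused stacks are reduced by global average pooling per channel before
classifier training, with provenance spans recording which source layer
contributed which channels. Pooling is the plumbing choice here — it is
parameter-free, size-agnostic, and standard practice for turning activation
maps into fixed-length descriptors. Real CNN activation extraction is out
of scope; generators produce synthetic stacks with the same geometry.

## Imbalance handling

Classes are split into *rich* and *poor* sets by an instance-count
threshold (default 1000; for the ISIC 2019 inventory any threshold in
(867, 2624] yields the same split: poor = {AK, DF, SCC, VASC}, 7.84% of
the data). Only poor-class images are augmented, online: each epoch draws a
fresh seeded variant, nothing is persisted, and rich-class images pass
through as the same array objects.

The augmentation bank applies, in fixed order (geometric then photometric):
horizontal/vertical flip, one centered affine combining rotation, shear,
zoom, aspect-ratio stretch and shift, random crop resized back, then
brightness, contrast, and Gaussian pixel jitter. Default magnitudes —
rotation ±30°, shear ±10°, zoom 0.8–1.2, aspect 0.9–1.1, shift ±10%, crop
90%, brightness/contrast ±20%, jitter σ = 0.02 on [0, 1] pixels — are
moderate dermoscopy-style settings; all are configurable and every draw is
made unconditionally in a fixed order so toggling one operator never shifts
another's randomness. Images are treated as [0, 1] float intensities;
geometric ops use reflect padding and restore the input size.

## Evaluation

The confusion matrix (rows true, columns predicted) yields one-vs-rest
counts per class and the four ratios: accuracy (tp+tn)/total, sensitivity
tp/(tp+fn), precision tp/(tp+fp), and F1 as their harmonic mean. Per-class
accuracy includes true negatives and is reported alongside the overall
micro accuracy (trace/total), which is the single headline number for a
multiclass experiment; macro averages are unweighted means over classes.
Zero-denominator ratios are NaN with a RuntimeWarning, never a silent zero
— with eight classes and small test batches, absent classes are common and
must be visible.

## Synthetic data

The generator emulates two-view deep features with class-conditional
Gaussian clusters: class k's mean sits `separation` within-class standard
deviations from the origin along coordinate axis k (distinct means are
separation·√2 apart), both views share labels and instance order, and each
view draws independent noise with its own scale so an inferior view can be
emulated. Defaults: 8 classes, 16 features per view, 100 instances per
class, separation 4 sd, unit noise both views.

What this does and does not show: passing recovery tests demonstrates the
decision-fusion machinery is correct and well-calibrated on data matching
its assumptions (unimodal classes, homoscedastic noise, independent view
errors). Real dermoscopy features are none of these — heavy-tailed,
correlated across views, with class overlap structure the generator does
not model — so synthetic accuracy says nothing about clinical performance.

Study-scale choices: the recovery suite uses 100 instances per class, a
stratified 80/20 split, and five seeds per condition; degradation is
checked over separations {6, 3, 1, 0} sd with a 0.02 Monte-Carlo slack on
the non-increasing ordering. At these sizes the full suite runs in well
under a minute on one CPU.

## Known limitations

* Calibration folds (default 3) need at least 3 instances per binary class
  per column; very small per-class counts require lowering
  `calibration_folds`.
* The false ensemble's scores are only as meaningful as its calibration;
  with near-separable data the sigmoid saturates and I collapses toward 0
  for all classes, making the all-zero branch rare.
* OvO scoring is an aggregation heuristic (see above), not a probability.
* The rich/poor threshold is a hard count cut; ratio- or quantile-based
  partitions are not implemented.
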