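# Methods

This note documents the models and procedures `wildtrap` implements,
the conventions it fixes where the underlying protocol leaves choices
open, and what the synthetic test-bed does and does not establish.

## The evaluation problem

A camera-trap inventory is a set of images, each labeled with one of
*K* classes (species, human activity, or "No Animal") and the camera
location it came from. Two properties dominate evaluation design:

1. **Long-tailed imbalance.** A few classes have thousands of images;
   many have tens. The packaged 55-class table spans 8,566 training
   images ("No Animal") down to 8 ("Woodrat").
2. **Location structure.** Each location has a static background, so
   images are not exchangeable: a classifier can exploit
   background–class correlations that break at new sites.

Correspondingly there are two protocols. The **trained-location**
protocol draws a single seeded permutation of all images and assigns
the first ⌈(1−f)·N⌉ to training (f = 0.10 by default). The
**untrained-location** protocol blocks by location: locations, in
their deterministic catalog order (first appearance in the manifest),
are cut into k contiguous blocks with boundaries `b_i = round(L·i/k)`
(half-up); fold *i* tests block *i* and trains on the rest, so
train-location and test-location sets are provably disjoint (the
pipeline re-verifies this at run time). Across-fold aggregates are
reported as mean ± population SD.

Conventions fixed here because the protocol does not specify them:
the location ordering behind the contiguous blocks is manifest order;
the random split is a single global permutation (not per-class
stratified); 5-image bursts may straddle the random split (sequences
are not grouped — a documented risk, not an error); the default test
fraction is 0.10 even though the packaged table's own counts imply
≈5% test overall — the discrepancy is documented, not emulated.

## Ratio-based rebalancing

Each class gets ratio `r_c = n_c / n_max` relative to the largest
training class. One emission of the training stream repeats up to *M*
times (default M = 10): draw a record uniformly from the whole
training set (class *c*), draw `u ~ U(0,1)`; if `u > r_c`, emit a
fresh uniform draw *within class c* and stop; otherwise redraw. Taken
literally the loop can never accept the largest class (`r = 1`), so on
cap exhaustion the last drawn record itself is emitted. With
`p_c = n_c/N` and `q = Σ_c p_c r_c`, the induced class distribution is

    P(c) = p_c (1 − r_c) (1 − q^M) / (1 − q) + q^(M−1) p_c r_c

(`P(c) = p_c` in the fully balanced limit `q = 1`). The test suite
and the acceptance script verify stream frequencies against this
closed form by independent enumeration at 10⁵ emissions (3σ), on a
grid of 2- and 3-class configurations. Two readings were fixed
deliberately: "a random sample of the same class" is a fresh uniform
within-class draw (not the originally drawn image), and ratios are
computed from training-set counts after the split, never from the
whole dataset (whole-dataset ratios would let test-set sizes influence
training).

**Supplementation** happens after the split, on training records
only: every class below `min_count` (the original study used 100) is
topped up to exactly `min_count` with augmented copies, sources cycled
in catalog order, augmentation seeds derived from `(seed, class, copy
index)`. Copies carry `is_augmented=True`; the split code forces such
records out of any test side, and drops them entirely when their
source location falls in an untrained-protocol test block.

## Augmentation

Eight label-preserving operators (mirror, channel shift, blur,
grayscale, rotation, pixel dropout, local contrast normalization,
small local affine warps), each with an application probability and a
magnitude range. Defaults are mild because no canonical magnitudes
exist for this protocol: rotation ±25°, blur σ ≤ 2 px, dropout ≤ 5% of
pixels, channel shift ±20 levels, affine displacement ≤ 8% of the
frame — ranges chosen so a small sprite stays recognizably itself.
"Pixel cluster normalization" is interpreted as local contrast
normalization over Gaussian neighborhoods (σ = 3 px); this is an
interpretation, recorded as such. `augment(image, config, seed)` is a
pure function, which is what makes supplementation copies "fixed".

## Metrics

precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), with
every 0/0 resolved to 0 — a class present in the test set but never
predicted scores 0 and *still counts* in the macro mean, deliberately
penalizing models that ignore rare classes. The single reported F1
per model is the **macro** (unweighted) mean over classes with nonzero
test support. Macro averaging is an inference: in single-label
multiclass classification micro-F1 is identical to top-1 accuracy (an
identity the tests assert), so only macro averaging can produce the
large accuracy-vs-F1 spreads that motivate reporting F1 at all.
Classes absent from training but present in an untrained-location test
fold stay in the metrics by default — the resulting degradation is the
phenomenon being measured, not a nuisance. Chance level for a uniform
guesser over 55 classes is 100/55 ≈ 1.81%.

## Recall versus training-set size

Per-class recall is binned by training-image count (default edges 500
and 1000, i.e. <500 / 500–999 / 1000+), each bin summarized by its
arithmetic mean and **population** SD (divisor n). The population
convention is established by recomputation: the packaged table's
1,000+ bin reproduces 0.971 ± 0.0137 with divisor n, while divisor
n−1 gives 0.0146. The two lower bins do *not* round-trip exactly from
the table's printed (3-decimal) recalls — recomputation gives 0.743
and 0.8945 against printed 0.750 and 0.874 — consistent with the
original analysis having used unrounded recalls; only the 1,000+ bin
is treated as exactly reproducible. Display rounding is 3 decimals
for recalls and 3 significant figures for SDs.

The trend fit regresses recall on ln(n_train) by ordinary least
squares. Its input points are the non-empty contiguous 500-wide bins,
each contributing (mean n_train of its classes, mean recall) — a
concrete convention for "mean of groupings per 500 images" whose exact
x-coordinates are otherwise unspecified; under it the packaged table
yields r² = 0.833. The guideline function returns the smallest bin
lower bound whose mean recall clears a target; at 0.95 the packaged
table answers 1,000+ images.

## Classifier backends

The backend contract is minimal: fixed ordered labels after fitting,
and `predict_proba` returning simplex vectors in that order. The
reference backend is multinomial logistic regression on 16×16
grayscale block-mean pixels with per-image mean subtraction (cheap
illumination invariance; night frames otherwise swamp shape), trained
with Adam (lr 0.05, β₁ 0.9, β₂ 0.999, weight decay 1e-4, batch 32, 40
passes by default) on minibatches drawn from the rebalanced, augmented
stream. It is bit-deterministic per seed and trains in well under a
second at desk scale — its role is to exercise every pipeline stage
and reproduce the *direction* of the domain-shift effect, not to rival
convolutional networks. The six GPU-scale architectures from the
original study (DenseNet201, Inception-ResNet-V2, InceptionV3,
NASNetMobile, MobileNetV2, Xception; transfer learning, Adam, 500
epochs) are registry entries behind the same contract; wiring them to
an external deep-learning stack is the user's choice and outside the
test suite.

Ensembles use hard plurality over top-1 votes; ties are broken by the
highest mean predicted probability among tied labels (the underlying
protocol says only that models "vote"); soft summed-probability voting
is available as an option. Ensembles are trained and evaluated per
fold in the untrained protocol. Tie-breaks in `predict_top1` go to
the lowest-index class.

## Synthetic worlds

The generator produces the statistical structure the analysis needs,
not photorealism: per-location static procedural backgrounds (layered
two-color gradient plus fixed elliptical "rocks/logs", so locations
are identifiable from pixels), species sprites from a small
shape/color/texture vocabulary with pose, scale, occlusion, crop and
day/night jitter, per-image sensor noise, exact per-class abundance
counts, a species×location binary occupancy matrix (default: each
species at a seeded ~60% of locations), an optional
motion-burst mode (5 frames, drifting pose), and a "No Animal"
majority class. Generation is a pure function of (config, seed) down
to byte-identical PNGs.

Default desk-scale conditions (frozen as the package's study
conditions): 6 locations, 5 species with geometric-decay abundances
(ratio 0.85 from a 70-image maximum) plus 84 empty frames, 64×64
images, noise σ 3, 15% night frames, 15% partial occlusion, 5%
cropped-out animals, background contrast 0.8. Under these conditions
the reference backend reaches ~0.67 trained-location accuracy and
~0.42 untrained-location accuracy (mean over 20 paired seeds), a gap
of ~25 points with a one-sided sign-test p < 10⁻⁶; collapsing all
locations onto one shared background (the `shared_background`
ablation) shrinks the mean gap to ~0, confirming location-specific
backgrounds as the mechanism. An `easy_world_config` preset
(balanced classes, full occupancy, extreme-luminance species, subdued
backgrounds) is constructed to be linearly separable and is used for
smoke checks that the training loop actually learns.

**What passing tests do not show:** synthetic sprites are rigid and
the backgrounds low-dimensional, so absolute accuracies here say
nothing about real imagery; background variability is not calibrated
to any real site; the desk backend's gap magnitude is not comparable
to convolutional models'. What the synthetic results *do* establish
is pipeline correctness (bookkeeping, leakage-freedom, determinism)
and the qualitative domain-shift mechanism.

## Numerical and degenerate-input conventions

Fold boundaries round half-up, so block sizes differ by ≤ 1 for any
(L, k). Empty recall bins report n = 0 with zero mean/SD and are
skipped by the guideline and the trend fit. The trend fit rejects
all-equal n_train (degenerate design) and n_train < 1. The stream
sampler requires ratio coverage of every catalog class; supplementation
refuses classes with zero non-augmented sources. Catalog loading
rejects duplicate image ids, missing required columns (named in the
error) and empty labels/locations (with the offending line number).
All randomness flows from explicit integer seeds; string-keyed RNG
streams use crc32, never Python's salted `hash`.
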