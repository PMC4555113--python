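# Methods

This note records the modelling choices behind `bowfood`, the defaults
and why they are what they are, and what the synthetic data generator
does and does not demonstrate.

## Pipeline overview

The pipeline is a classical bag-of-visual-words classifier specialized
for multi-food photographs:

1. **Normalization.** Images decode to 8-bit RGB; greyscale inputs are
   replicated, alpha is dropped, EXIF orientation is ignored. If either
   side exceeds 2000 px the image is halved once (floor division, BOX
   area-average resampling). The rule is deliberately not iterated: it
   is a speed/keypoint-thinning heuristic, not a size normalization.
2. **Detection.** Difference-of-Gaussian scale-space extrema with
   sub-pixel refinement, low-contrast and edge rejection, and dominant
   gradient orientation (scikit-image's SIFT detector). The contrast
   threshold is permissive (`c_dog = 0.004`): codeword histograms need
   tens of keypoints per image to be stable, and small or low-contrast
   images fall below the conventional threshold's yield. Greyscale
   intensity is the channel mean.
3. **Description.** All three channels share one patch geometry: a
   square of side `round(12·scale)`, at least 16 px, centred on the
   point and clipped to the image. The shape channel resamples the
   patch on a 16×16 grid rotated by the keypoint orientation and
   accumulates gradient magnitudes into a 4×4×8
   position–orientation histogram with trilinear soft-binning and
   Gaussian radial weighting, then L2-normalizes with the standard
   0.2 clamp-and-renormalize. The texture channel is the 59-bin
   non-rotation-invariant uniform LBP(8,1) histogram, L1-normalized,
   with the patch's one-pixel border excluded (codes there would read
   pixels outside the patch). The colour channel is the joint 4×4×4
   RGB histogram over equal-width bins [0,64), [64,128), [128,192),
   [192,256), L1-normalized; the joint (64-bin) rather than
   concatenated (12-bin) form preserves channel co-occurrence. A
   whole-image variant (`colour_histogram_global`) is provided for
   completeness but is not part of the default pipeline, which keeps
   all three channels local so each can feed its own codebook.

   Under scikit-image's LBP convention a bit is set when a neighbour is
   ≥ the centre, so a perfectly flat patch maps to the all-ones uniform
   pattern (one bin carries all the mass). Only the convention, not the
   substance, differs from descriptions that assign flat patches to the
   all-zeros pattern.
4. **Quantization.** One codebook per channel, built from descriptors
   pooled over *all* training images (shared vocabularies, not
   per-category ones — the standard BoW arrangement, and the only one
   consistent with a single concatenated histogram). Lloyd's algorithm
   runs with chi-squared assignment and arithmetic-mean updates; exact
   chi-squared centroids have no closed form, and the mean is the
   standard surrogate. Because the mean update is only approximately
   optimal under chi-squared, an explicit guard stops iteration if the
   objective would rise, keeping the recorded objective monotone per
   run. Initialization is k-means++ under the chi-squared metric;
   empty clusters are re-seeded with the point farthest from its
   centroid; iteration stops on unchanged assignments or at 300
   iterations. `n_init` restarts (default 3; raised to ≥ 25 for pools
   of ≤ 100 points, where local optima are actually reachable and
   restarts are free) keep the best objective. Pools larger than
   `max_codebook_features` (default 6000 per channel) are subsampled
   with a seeded generator — the usual way to bound K-means cost.
   Default codebook sizes are 100 (shape), 40 (texture), 50 (colour),
   concatenating to a 190-bin histogram.
5. **Encoding.** Per channel, codeword counts over all points,
   L1-normalized *per channel* before concatenation so that channels
   with different vocabulary sizes and a common point count carry equal
   weight. An image with zero interest points raises an explicit
   unencodable-image error; batch callers log and skip (training) or
   score it as never-recognized (evaluation).
6. **Classification.** One-vs-rest soft-margin linear SVMs (squared
   hinge, primal solver, so retraining is bit-reproducible). A
   multi-label training image is a positive for every category it
   contains. Two choices deserve explanation:

   * *Cost convention.* The loss term is a weighted **mean** over
     samples (effective per-sample cost `C/n`), which makes the fitted
     boundary exactly invariant to duplicating the training set — a
     property we consider part of the estimator's contract. In this
     convention the familiar "C = 1" of per-sample-cost libraries
     corresponds to C ≈ n, not 1; with a few dozen training images a
     total budget of 1 produces near-degenerate classifiers. The
     default is therefore `C = 64`: a per-class misclassification
     budget of order the training-set size, i.e. the standard
     per-sample operating point for study-scale data. It is exposed in
     `PipelineConfig.regularization`.
   * *Class weighting.* Inverse-frequency ("balanced") weighting is on
     by default: with 4–8 positives against ~50 negatives per
     category, unweighted fits collapse toward the majority class.

   Between encoding and classification the pipeline applies a
   **Hellinger map** (element-wise square root of the histogram,
   `PipelineConfig.hellinger`, default on): a linear kernel on
   √-histograms approximates the chi-squared kernel, matching the
   metric the vocabulary was built under, and measurably improves
   multi-food images, whose histograms are mixtures. The encoder's
   output contract (L1-normalized blocks) and the scorer's contract
   (literal `w·h + b`) are unchanged; the map is a pipeline step
   applied identically at train and test time.
7. **Prediction.** Single-label: argmax of the decision scores, ties
   to the earlier category in the model's (sorted) category order.
   Multi-label: every category with score **strictly** greater than
   the sensitivity ε; the set may be empty.
8. **Evaluation.** Per category, the Jaccard index between the
   recognized set and the truth set, maximized over ε. Candidate
   thresholds are `s − 10⁻⁹` for every distinct observed score plus
   `max + 10⁻⁹`; under the strict-inequality rule this grid realizes
   every achievable recognized set, so the maximum is exact, and the
   smallest maximizing ε is reported. The overall figure is the
   unweighted category mean — the aggregation that reproduces the
   published table's overall row (a mean of 0.376 printed as 0.37, and
   0.465 printed as 0.47; the printed values round inconsistently, so
   agreement is to one unit in the second decimal). If recognized and
   truth sets are both empty the Jaccard index is defined as 1
   (nothing to find, nothing claimed) and the event is logged.
   Ablation studies (per-channel columns) share feature extraction and
   per-channel codebooks — a codebook depends only on its own channel
   — and retrain only the classifiers.

## Serialization

Codebooks, classifier weights, the configuration, and a SHA-256
checksum of the centroid matrices travel together in a single `.npz`
archive with a format-version field. The checksum is verified on load,
so classifiers can never silently be applied to histograms encoded
against different codebooks. Archives are written atomically (temp file
+ rename); a failed write leaves nothing behind.

## The synthetic data generator

The generator emulates the *structure* of a small multi-food photograph
study: 10 categories, 4–8 single-label training images each, 13–20 test
rows per category, 30% of test rows multi-label composites of 2–5
categories, 128×128 px, with a global illumination factor drawn from
[0.9, 1.1] per test image (within the wider nominal [0.7, 1.3] range so
the colour channel is perturbed but not dominated). Each category is a
colour/texture/shape signature: base colours sit at quantization-bin
centres (32/96/160/224 per channel) so ±10% illumination never moves an
item across a colour bin; texture modulations (stripes, band-limited
speckle, additive blobs) are shallow enough to stay within a bin while
remaining visible to LBP, which reads the sign pattern of local
differences; item grain is band-limited rather than white so a
scale-space detector can see it. Two categories, `custard` and `milk`,
are rendered identically except for base colour and exist to make
channel ablations interpretable: dropping the colour channel must
collapse exactly that pair.

Categories are separable **by construction**. That is the point: the
generator provides ground truth against which end-to-end recovery can
be asserted (the suite requires overall r ≥ 0.9 with combined features
on the default profile, and a ≥ 0.3 drop for the colour-only pair under
colour ablation). Passing these tests shows the pipeline faithfully
recovers signal that is present; it says nothing about photographs of
real food, where categories overlap in all three channels, backgrounds
are cluttered, and illumination varies in hue as well as intensity —
real-data accuracies in this family of methods are far lower. The
generator also does not emulate camera noise, perspective, occlusion
between items, or portion size.

## Numerical and degenerate-input conventions

* Chi-squared terms with zero denominator contribute 0 (both entries
  are then 0, the limit of the term).
* Codeword assignment breaks ties toward the lowest index; single-label
  prediction breaks score ties toward the earlier category.
* A constant image legitimately has no interest points: detection
  returns an empty list, encoding raises, prediction flags the image
  (`"encodable": false`) with exit code 0, evaluation counts it as
  never recognized and logs it.
* K-means requires at least K distinct features and is bit-reproducible
  for a fixed seed; all randomness in the package flows from explicit
  seeds.
* Evaluation refuses manifests whose train and test splits share a
  path, and refuses test labels absent from the trained model.

## Problem sizes

Defaults are sized for a workstation: the study-scale profile
(~50 train images, ~170 test rows at 128×128) extracts features in
under a minute and builds its three codebooks from ≤ 6000 pooled
descriptors per channel in a few tens of seconds; the full ablation
study runs in about a minute on one CPU.
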