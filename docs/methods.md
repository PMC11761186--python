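# Methods

## Overview

`attnsig` implements an end-to-end histology-to-prognosis analysis: an
attention-augmented convolutional classifier produces a per-image
"H&E-based survival score" (the predicted probability of long overall
survival), survival statistics evaluate that score, gene-set enrichment
contrasts expression between low- and high-score groups, and a spatial
module correlates the model's attention signal with per-spot immune
signature enrichment on Visium-style samples. Because the analysis is
exercised on synthetic data, every stage has planted ground truth and the
test suite can check parameter recovery and statistical calibration
rather than visual plausibility.

## The classifier

The network is a four-stage strided convolutional backbone with two
*interpolation attention* modules and a three-layer fully connected head:

* Attention module 1 pairs stages 1 and 2: the stage-2 map is projected
  to one channel by a learned 1x1 convolution, squashed by a sigmoid,
  bilinearly upsampled (corner-aligned) to the stage-1 grid, multiplied
  elementwise into the stage-1 features, and global-average-pooled to a
  vector of stage-1 width. Module 2 does the same with stages 3 and 4.
* The backbone ends in global average pooling and a linear layer to its
  output width. The concatenation [backbone output, pooled attention 1,
  pooled attention 2] feeds the head (128, 32, 2 units; ReLU and dropout
  0.2 after each hidden layer; softmax output).
* With the `resnet101-like` configuration (stage widths 256/512/1024/2048,
  backbone output 1000) the concatenated vector is 2280 wide and the
  pooled attention vectors are 256 and 1024 wide. The `tiny` configuration
  (8/16/32/64, output 50; concat width 90) has the same topology at a
  scale that trains in seconds on one CPU; desk-scale results in the test
  suite use it at 64 px input.

The backbone keeps the stage channel widths that determine these
arithmetic facts but uses one convolution block per stage; reproducing
the reference backbone's exact depth or pretrained weights is a non-goal,
and no pretrained weights are bundled (`pretrained=True` is rejected).

The network, its backward pass, and the Adam optimizer are implemented
directly on numpy (im2col convolutions, explicit layer-by-layer
gradients). The full-network backward pass is verified against central
finite differences in float64 in the test suite.

**Loss.** Training minimises the focal loss, the mean over the batch of
`-alpha * (1 - p_t)^gamma * ln(p_t)` where `p_t` is the probability
assigned to the true class; `gamma=2, alpha=0.25` by default (the
standard published defaults; configurable). Probabilities are clamped at
`1e-7` inside the logarithm. At `gamma=0, alpha=1` the loss reduces
exactly to the negative log-likelihood, which the tests assert.

**Optimization.** Adam with learning rate 2e-4 and step decay (factor
0.1 every 7 epochs) by default; the desk-scale profile uses 1e-3 because
the tiny backbone at 64 px otherwise needs many more epochs than the
budgeted six.

## Attention maps and their sign

`attention_heatmap` returns module 2's sigmoid gate, bilinearly upsampled
to image resolution and min-max normalized to [0, 1] (a constant map
normalizes to zeros). This raw gate is, however, *sign-ambiguous*: the
head can absorb an inverted gate (suppress informative regions and read
the complement), so nothing forces high gate values onto the regions that
drive the prediction — on the synthetic task trained models orient the
raw gate either way at roughly equal rates.

For overlays and spatial integration the package therefore also provides
`attention_saliency`: the gate multiplied by the sensitivity of the logit
margin to it, `M = g * d(logit_1 - logit_0)/dg`, evaluated on the gate's
grid, upsampled and min-max normalized. This score-weighted reading
orients the map toward regions that *support* the long-survival class and
is the signal used by the workflow's overlay and spatial stages. It
resolves the sign in most trained runs, but not all: a trained head may
genuinely invert the attention path, and the orientation of desk-scale
attention maps remains a stochastic property.

## Cohort preparation and training protocol

* Inclusion: stage I/II records are excluded; a missing stage is imputed
  as III so the record is retained.
* Label: target 1 iff overall survival is at least 36 months. Only
  uncensored records enter label construction (their event time is known
  exactly); censored records are kept for Kaplan-Meier evaluation.
* Images: a square image yields one training tile; a rectangular image
  yields two squares taken from the two ends of its long axis, all
  resized to the working resolution. Training uses every tile;
  validation, testing and scoring use the first tile only.
* Augmentation (training only, seeded): horizontal/vertical flips,
  multiples of 90 degrees plus a small random angle (+-15 deg), random
  shear/translation up to 10%, then per-channel standardization.
* Cross-validation: a balanced k-fold split (k=5) over image ids by
  default — the reference protocol's choice, with a leakage-safe
  patient-level split available via `groups`/`patient_of`. Per fold,
  training is repeated several times (default 5) for a fixed number of
  epochs (default 10); validation AUROC is computed after every epoch and
  the single checkpoint with the best AUROC across repeats x epochs is
  selected (ties to the earliest).
* Ensemble score: the mean positive-class probability of the k selected
  fold models on an image's first tile. "Positive" means long survival;
  a convention, exposed through the `positive_class` argument.

## Survival statistics

All implemented from first principles (scipy supplies only distribution
tail functions): Kaplan-Meier product-limit curves; the two-group
log-rank test with hypergeometric variance at each distinct event time
(`chi2 = (sum O1 - sum E1)^2 / sum V`, 1 df, no continuity correction);
AUROC as the normalized Mann-Whitney statistic on mid-ranks; the
step-wise cutoff search evaluating the log-rank p at every midpoint
between consecutive distinct scores, subject to each group holding at
least `min_group_frac` (default 0.1) of the samples, ties resolving to
the lower cutoff; the Mantel-Haenszel hazard ratio `(O1/E1)/(O2/E2)` with
a log-scale normal 95% interval (`SE = sqrt(1/E1 + 1/E2)`) — an
approximation, flagged rather than raised when a group has no events;
and the 2x2 Pearson chi-square. The median split used for enrichment
grouping assigns ties at the median to the low group (strict inequality
for "high").

## Enrichment statistics

* **GSEA.** Genes are ranked by signal-to-noise between the two phenotype
  groups, `(mu1 - mu0)/(s1 + s0)` with each class standard deviation
  floored at `max(0.2 * |mu|, 0.2)`. A set's enrichment score is the
  signed extremum of the weighted Kolmogorov-Smirnov running sum (hit
  increments proportional to `|metric|^weight`, default weight 1,
  normalized to sum to one; miss decrements `1/(N - N_hit)`). The null is
  phenotype permutation with seeded shuffles; p-values are sign-matched
  (`(count + 1)/(n_same_sign + 1)`), NES divides the ES by the mean
  same-sign null magnitude, and FDR follows the sign-matched NES-ratio
  procedure. Empirical type-I error at the 0.05 level is checked to lie
  in [0.03, 0.07] over 500 null sets in the acceptance suite. Sets
  overlapping the universe in fewer than `min_size=5` genes are dropped.
* **ssGSEA.** Genes are ranked by expression descending; the score is the
  sum over ranks of the normalized `rank^alpha`-weighted in-set
  cumulative fraction minus the uniform out-of-set cumulative fraction
  (alpha 0.25). The score is invariant under strictly increasing
  transforms of the expression vector, so the default per-spot
  normalization (library-size normalize, log1p) only matters through
  ties.
* **Benjamini-Hochberg** step-up adjustment is provided for generic
  p-value lists. The conventional significance rules (p < 0.05,
  FDR < 0.25) are configuration values, not hard-coded filters.

## Spatial integration

A Visium-style bundle (MatrixMarket counts, features/barcodes TSV,
positions CSV with full-resolution pixel coordinates, scale-factor
sidecar) is joined into a `SpotTable`. Per spot, attention is the mean
heatmap value over pixels within the scaled spot radius of the scaled
center (nearest-pixel lookup for sub-pixel radii). Spots are clustered by
a deliberately simple, deterministic stand-in for neighborhood-graph
clustering: library-size normalize, log1p, top 200 variable genes, PCA to
at most 20 components, seeded k-means. The tumor cluster is the one with
the highest mean normalized marker expression (ties to the larger
cluster); markers are user-supplied, with synthetic defaults. The final
statistic is the Spearman correlation (Pearson on mid-ranks, t
approximation for p) of `ln(attention + 1e-6)` with the per-spot ssGSEA
score, restricted to the tumor cluster by default. Coordinates follow the
image convention: x = column, y = row, origin top-left; the scale factor
multiplies full-resolution positions.

## Synthetic data: what it emulates, and what it does not

* **Tissue tiles** are a pink stromal field with smooth texture noise,
  2-4 purple elliptical "tumor nests", and immune infiltrate rendered as
  spatial clusters of small dark blobs whose total area fraction
  approximates a target density `d` (within +-0.05 in tests). The blobs
  are a learnable texture with an exact ground-truth mask, not realistic
  nuclei; stain physics, scanner variation and pyramid resolutions are
  not modeled.
* **Survival** is exponential: OS rate `h0 * exp(-beta * d)` with
  `beta = 2` (denser infiltrate, longer survival). The baseline hazard
  defaults to `h0 = ln2 * e / 35 ~ 0.054 / month`, chosen so the marginal
  median OS is ~35 months — the cohort median the analysis is modeled on —
  which also balances the 36-month label (~49% positive). Censoring is
  independent uniform truncation with probability 0.2 by default.
  Progression-free survival is a uniform fraction (0.25-0.75) of OS.
  Under these hazards the label carries limited information about `d`:
  the AUROC of the *true* density against the 36-month label is ~0.71
  asymptotically, which bounds what any image model can achieve — the
  end-to-end recovery checks are designed around this ceiling, with a
  test split large enough (~200 labeled patients) that sampling noise
  does not dominate it.
* **Expression** is negative binomial (dispersion 0.5, log-normal library
  sizes, sigma 0.2) with signature-gene means scaled by
  `1 + (fold_change - 1) * d` per patient, or per spot by the infiltrate
  fraction `f_s` inside the spot disc. Spots whose capture disc lies
  majority inside a tumor nest are "tumor" and express a marker program
  (4x by default); this binary planting makes tumor-cluster recovery a
  well-posed task (continuous marker gradients leave boundary spots
  genuinely ambiguous).
* **Spot geometry** is a square lattice (pitch ~ image/12, radius 0.35 x
  pitch) rather than the hexagonal Visium layout; pitch and radius are
  configurable to mimic the 100 um pitch / 55 um spot geometry.

Passing tests on these generators demonstrate that the pipeline recovers
planted effects of realistic shape and that its statistics are calibrated;
they say nothing about performance on real slides, scanners or cohorts.

## Desk-scale problem sizes

The default test/workflow profile uses 64 px tiles, the tiny backbone,
420 patients (60% held out for testing), 5 folds x 2 repeats x 6 epochs,
400 genes, 200 GSEA permutations, and a 160 px spatial sample (~140
spots). These sizes keep a full pipeline run around two minutes on one
CPU while leaving the planted effects detectable; `RunConfig.full_scale`
records the reference-protocol settings (1024 px, resnet101-like, 5x10
epoch repeats, learning rate 2e-4) for use on real hardware.

## Known limitations

* The attention-gate orientation is not identifiable on the synthetic
  task (see above); the score-weighted saliency usually, but not always,
  resolves it.
* Image-level cross-validation leaks patients across folds when a patient
  contributes two images; it is the default for fidelity to the reference
  protocol, and patient-level splitting is one argument away.
* The hazard-ratio interval is a normal approximation; the step-wise
  cutoff's p-value is not corrected for the multiplicity of the search.
* The numpy network is single-threaded apart from BLAS matmuls; the
  resnet101-like configuration is practical for forward passes at modest
  resolutions, not for full-scale training.
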