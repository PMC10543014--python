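# Methods

This note documents the models, conventions and design choices behind
`pruneaudit`: what each stage computes, what the synthetic data emulate
(and what they do not), and where the genuinely open decisions were made.

## Pruning model

Global unstructured L1 pruning: given a trained weight set with P prunable
elements (weight matrices only; biases are excluded, following standard
magnitude-pruning practice and keeping the sparsity ratio interpretable),
pruning at ratio k zeros exactly `floor(k·P)` elements — those of smallest
absolute value ranked *jointly across all prunable tensors*, not per layer.
Pruning is one-shot and post-training; no fine-tuning or iterative
prune–retrain is performed.

Ties at the magnitude threshold are broken by a fixed total order (tensor
name order, then flat index) so results are bit-reproducible. Pre-existing
zeros sort first under this order, which yields two useful invariants that
the test suite asserts across the full grid:

- **Nestedness** — the zero set at k is a subset of the zero set at k′ ≥ k;
- **Idempotence** — pruning twice at the same k is a no-op the second time.

## Evaluation

Average precision is the primary metric: it is threshold-free and robust to
the extreme negative/positive imbalance of tail classes, where AUROC
inflates. The implementation is the non-interpolated step-wise AP with
tied scores processed as a single threshold group, making the value
independent of the ordering of tied samples; it agrees exactly with an
exhaustive all-thresholds precision–recall oracle and with scikit-learn's
reference implementation on random tied instances (both asserted in
tests). A class with zero positives has no defined AP; such entries carry
a NaN marker and are excluded from means rather than imputed — imputing 0
would fabricate forgetting signal for empty classes.

Welch's unequal-variance t-test (two-sided) compares per-run mean AP
between the unpruned and each k-sparse population; the significance sweep
reports the smallest k with p below α = 0.001 *and* a lower mean — a
significant increase never counts as a drop. No multiplicity correction is
applied across the grid comparisons; the full per-k table is written so a
reader can apply one.

## Forgettability analytics

The forgettability curve of class c is, per grid point k, the median over
runs of the relative AP change from that run's unpruned model to its
k-sparse counterpart. Relative (not absolute) change makes impact
comparable across classes of different difficulty; the median over runs
(mean of the two central order statistics for even run counts) damps
run-to-run variance. The k = 0 point is exactly 0 by construction. Classes
whose median baseline AP falls below a floor of 1e-3 are excluded with a
structured warning — relative change is numerically meaningless there.

Two summary statistics per class: the *first-forgotten sparsity* (smallest
grid k with a median relative drop of at least 20%) and the *tail impact*
(curve value at the grid maximum, 0.95). Classes that never reach the drop
are censored and recorded as 1.0 — just above the grid maximum — so robust
classes stay in rank correlations instead of being discarded.

FCD between two classes is the mean squared error between their curves; it
is a pseudometric (nonnegative, symmetric, zero on identity, and its square
root satisfies the triangle inequality). Pairwise covariates are computed
on the test split: label IoU and the absolute difference of natural-log
class frequencies (the log base only rescales the regression coefficient;
the output metadata records base e). The OLS model
`FCD ~ 1 + |LogFreqDiff| + IoU^¼ + |LogFreqDiff|·IoU^¼` is fit on raw
covariates via statsmodels, with a rank check that names collinear columns.
Frequency covariates default to training counts for per-class forgetting
correlations and test counts for the pairwise analysis.

## Pruning-identified exemplars

Per test image, agreement is the Spearman correlation (average ranks on
ties) between the C class scores of the population-average unpruned
prediction and the population-average prediction at the comparator
sparsity (0.9 by default, configurable). "Bottom 5th percentile" is
operationalized as a rank rule — exactly `floor(0.05·N_defined)` lowest
correlations, boundary ties broken by image index — which guarantees a
deterministic, exact flag rate; the interpolated percentile threshold is
reported alongside for transparency. Images with constant prediction rows
(undefined rank correlation) are excluded from the ranking rather than
assigned 0, which would force them into the PIE set artifactually.

Enrichment is reported as the ratio of class prevalence (and of
disease-count bucket frequency, d ∈ {0, 1, 2, 3, 4+}) among PIEs relative
to non-PIEs, with an undefined marker wherever the non-PIE denominator is
empty.

## Synthetic data

The generator stands in for large long-tailed multi-label CXR corpora.

- **Labels.** A latent Gaussian vector with correlation matrix R is
  thresholded per class at the quantile matching the requested marginal
  prevalence (multivariate probit). This controls marginals and pairwise
  association independently; requested pair strengths are installed in R
  and projected to the nearest PSD correlation matrix, with a structured
  error naming pairs the projection cannot honour. Prevalence interpolates
  log-linearly from head to tail (default 0.3 → 0.002 over 20 classes, a
  150× span standing in for imbalance that reaches three orders of
  magnitude at full scale).
- **At least one label.** Rows drawn all-negative are backfilled on class
  0 — the most prevalent class, playing the role of a "No Finding" label —
  keeping N fixed.
- **Features.** Each class has a fixed Gaussian prototype in feature space;
  an image's features are the sum of its classes' prototypes scaled by
  per-class signal strength, plus isotropic Gaussian noise. Signal strength
  interpolates log-linearly (default 2.5 at the head to 0.35 at the tail):
  rare findings are also harder to see, which is what makes them
  forgettable rather than merely rare.
- **Rare-resembles-common.** The five rarest classes' prototypes are
  rebuilt to have cosine 0.85 with one head-class prototype each. A rare
  finding that mimics a common one must be discriminated by a fine residual
  feature; the network encodes that residual in small, distributed weights,
  which are exactly what magnitude pruning removes first. This is the
  mechanism by which heavily pruned models disagree with unpruned ones on
  rare-disease images.
- **Grouping and splits.** Samples are grouped into synthetic patients of
  1–3 images; groups are shuffled and greedily assigned to train/val/test
  targeting 70/10/20, so no patient straddles splits and achieved fractions
  are within one group's size of the targets.
- **Prediction fixtures.** For testing the PIE stage without training, a
  pair of score matrices where an `agreement` fraction of rows are strictly
  monotone transforms of each other (per-row rank correlation exactly 1)
  and the rest are independent redraws.

What the generator does *not* emulate: image content and augmentation,
label noise and report-parsing artifacts, inter-patient heterogeneity
beyond grouping, calibrated score distributions of deep networks, and
realistic co-occurrence graphs (only pairwise latent correlations are
controlled). Passing end-to-end tests therefore show that the *analysis
machinery* recovers planted long-tail structure — not that any particular
clinical system behaves this way.

## Classifier backend

A one-hidden-layer dense network (default 256 ReLU units) with elementwise
sigmoid outputs, trained by plain minibatch gradient descent (batch 128,
fixed learning rate 3.0) on the mean binary cross-entropy over samples and
classes, implemented in numpy with manual backpropagation. Everything —
initialization and minibatch order — flows from one seeded generator, so
training is bit-deterministic. An optional L2 weight penalty (off by
default) is available; it concentrates the weight-magnitude distribution
and makes models dramatically more robust to magnitude pruning, which is
itself a useful experimental contrast. Population training runs R
independent seeds (seed base + run index) and records test predictions for
every grid sparsity, with the k = 0 entry equal to the unpruned model's.

The default scenario trains for 10 epochs. This is deliberate
under-training: a network trained to interpolation scores its test
predictions at saturation (0 or 1), erasing the graded "differential
diagnosis" structure in the score vectors that the per-image agreement
analysis depends on; real disease classifiers operate far from
interpolation. Ten epochs leave the baseline imperfect and graded across
the frequency spectrum while head classes are still learned essentially
perfectly.

## Reference study conditions

The default experiment: C = 20 classes, N = 5000 samples, D = 64 features,
prevalence 0.3 → 0.002, noise 1.0, R = 10 runs, grid {0, 0.05, …, 0.95},
PIE comparator 0.9 and fraction 0.05, α = 0.001. On one CPU a full run
takes a few seconds; the acceptance script and the end-to-end tests use
these sizes directly.

Under these conditions the qualitative long-tail findings reproduce
robustly at the sign level: class frequency correlates positively with
both the first-forgotten sparsity and the tail impact, and pairwise IoU
correlates negatively with FCD, in essentially every replicate. One
statistic is intrinsically fragile at this scale and is worth flagging:
the PIE class-enrichment comparison between the 5 rarest and 5 most common
classes. With tail prevalence 0.002 and a 1000-image test split, each of
the rarest classes has only ~2–10 test positives, so the mean enrichment
ratio is dominated by whether a handful of individual images cross the 5%
PIE boundary; across replicates the comparison comes out in the expected
direction only about 55–60% of the time, versus the near-certain sign
recovery of the correlation statistics. Scaling the test split up (or the
tail prevalence) sharpens this statistic; at the reference desk scale it
should be read as an illustration, not a stable estimate.

## Numerical conventions

- Percentiles use linear interpolation on sorted values (numpy's default).
- Spearman and Pearson delegate to scipy; constant inputs return an
  undefined marker (NaN) rather than raising, so sweeps can proceed.
- Sigmoid is computed in the numerically stable split form; BCE clips
  probabilities at 1e-12.
- The latent correlation Cholesky adds 1e-9 to the diagonal to tolerate
  semidefinite (rank-deficient) requests.
- Serialized artifacts: datasets and weights as NPZ with a JSON sidecar;
  AP tables and curves as long-format CSV; regression fits and PIE
  summaries as JSON; every experiment directory carries a manifest with
  the config hash, run seeds and artifact hashes, sufficient to reproduce
  every artifact byte-identically.
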