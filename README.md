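# pruneaudit

Audit what magnitude pruning makes a classifier forget — for long-tailed,
multi-label problems like chest-X-ray disease classification, where a few
findings are common, most are rare, and one image can carry several labels
at once.

Modern disease classifiers are heavily overparameterized, so global L1
(magnitude) pruning — zeroing the fraction *k* of weights with the smallest
absolute value — barely moves headline metrics until *k* gets large. The
danger hides below the headline: the damage is not spread evenly across
classes or images. `pruneaudit` provides the machinery to quantify that
differential damage on a population of independently trained models:

- **Forgettability curves.** For class *c* and sparsity *k*, the median over
  runs *i* of the relative AP change
  `med_i { (AP_{i,k,c} − AP_{i,0,c}) / AP_{i,0,c} }`, traced over the grid
  `k ∈ {0, 0.05, …, 0.95}`. Per-class average precision (AP) is the base
  metric because AUROC inflates under heavy class imbalance.
- **Forgettability Curve Dissimilarity (FCD).** The mean squared error
  between two classes' curves, modelled by OLS on the absolute log class
  frequency difference, the fourth root of the pairwise label IoU
  (a co-occurrence measure), and their interaction:
  `FCD ~ β0 + β1·|LogFreqDiff| + β2·IoU^¼ + β3·|LogFreqDiff|·IoU^¼`.
- **Pruning-identified exemplars (PIEs).** Per test image, the Spearman rank
  correlation between the population-average prediction vectors of the
  unpruned and the 90%-sparse models; the bottom 5% of images are flagged
  and characterized by class and disease-count enrichment.
- **Significance sweep.** Welch's t-test between per-run mean AP at *k*=0
  and each *k* > 0 locates the first sparsity with a significant drop.

Because the real CXR corpora are large and access-controlled, the package
ships a first-class synthetic data module: a correlated-latent-Gaussian
(multivariate probit) label model with controllable long-tailed prevalence,
pairwise co-occurrence, at-least-one-label backfill, patient-level grouping
and a 70/10/20 group split, plus a tiny dense-network training backend —
so every stage of the analysis is testable at desk scale.

## Worked example

`examples/03_forgettability_curves.py` trains a 5-run population on a
10-class long-tailed scenario (head prevalence 0.3 → tail 0.005, rare
classes given weaker feature signal), prunes along the grid, and summarizes
each class's curve:

```
    class  train n  first 20% drop  change @0.95
 class_00     1472            0.95         -0.22
 class_01      444            0.90         -0.24
 class_02      240            0.90         -0.75
 class_03      163            0.85         -0.92
 class_04      101            0.85         -0.95
 class_05       76            0.60         -0.97
 class_06       36            0.50         -0.98
 class_07       25            0.45         -0.96
 class_08       12            0.55         -0.94
 class_09       15            0.40         -0.95

Spearman(first-forgotten sparsity, train frequency) = 0.92 (p=0.000157)
```

Reading the table: the head class (1472 training positives) does not lose
20% of its AP until 95% sparsity and ends with a −22% relative change,
while the rarest classes are forgotten by 40–55% sparsity and are nearly
erased (−94% to −98%) at 95% sparsity. The Spearman correlation of +0.92
summarizes the pattern: **the rarer the class, the earlier and the harder
pruning forgets it.**

The other examples cover dataset generation (`01`), single-model pruning
and weight-magnitude histograms (`02`), the FCD regression (`04`), PIE
detection on prediction fixtures (`05`), and the full orchestrated
experiment with all artifacts and a reproducibility manifest (`06`).

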