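# painrank

Gene-centred prioritization of candidate **pain genes**.

Only a few hundred genes carry experimentally validated ("gold
standard") evidence of a causal role in pain — knockout phenotypes in
mice or causal variants in human neuropathic-pain families — while
thousands of others are touched by injury-responsive expression changes
in the somatosensory system. `painrank` treats candidate discovery as a
severely imbalanced binary classification problem (roughly one labelled
pain gene per 40 non-pain genes): engineer a per-gene feature vector
from genomic annotation, multi-omics fold changes, Gene Ontology
membership and protein–protein-interaction (PPI) network topology, then
train an ensemble of probabilistic classifiers whose class-1
probability is reported as a per-gene **pain score** and used to rank
the genome.

It is written for computational biologists who want a self-contained,
testable implementation of this kind of prioritization pipeline: every
stage runs on a built-in synthetic cohort that reproduces the
statistical structure the analysis assumes (hub-enriched positives, GO
terms at elevated odds in positives, per-tissue log-fold-change effects
in a subset of positives), so no external downloads are required.

## Method

**Features.** Per gene: ordinal-coded categorical annotations
(compartment, tissue, chromosome), GC content, conservation, two PCA
components of a TF-IDF-weighted GO term matrix (terms in ≥ 20 % of
genes, and any term whose name contains "pain", are excluded),
composite log2 fold changes per (tissue, species) dataset group — each
entry zeroed unless significant at FDR < 0.05 before group-averaging —
TPM expression columns, and eleven PPI node centralities (degree, edge
count, average shortest path, betweenness, closeness, clustering
coefficient, eccentricity, neighborhood connectivity, radiality,
stress, topological coefficient). Features are min–max scaled to
[−1, 1] and correlation-filtered (|r| ≥ 0.75 drops the lower-variance
member); all transform parameters are fitted on the 70 % training split
only.

**Model.** Four base learners — XGBoost, gradient boosting, AdaBoost,
random forest — are combined by weighted soft voting:

    p(x) = Σₖ wₖ pₖ(x) / Σₖ wₖ ,   ŷ = 1{p(x) ≥ 0.5}

with the weight vector chosen by exhaustively permuting the multiset
{4, 2, 1, 3} over the members and keeping the permutation with the best
out-of-fold geometric mean. Each member trains on all positives plus
its own equal-sized random subsample of negatives. A stacking variant
(logistic meta-model on out-of-fold base probabilities) is available.

**Evaluation.** Selection and benchmarking use four imbalance-robust
metrics from the confusion matrix:

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    GM  = √(sensitivity · specificity)
    F1  = 2·precision·recall / (precision + recall)
    BA  = (sensitivity + specificity) / 2

**Validation of the ranking.** A running-sum (unweighted
Kolmogorov–Smirnov) enrichment score against independent gene sets,
with a gene-label permutation null and add-one p-value, run with and
without removal of training-labelled genes (leakage removal); plus
hypergeometric over-representation of annotation terms in the top and
bottom deciles with Benjamini–Hochberg adjustment. Feature importance
uses tree-path attribution, combined across members by the voting
weights, and drives backward feature elimination.

## Worked example

```python
from painrank import simulate
from painrank.model import PainGeneClassifier

cohort = simulate.generate(simulate.SimConfig(n_genes=800, seed=3))
model = PainGeneClassifier.from_cohort(cohort)
res = model.fit(cv_folds=5)
print(res.summary())
```

```
Pain-gene prioritization results
==========================================================
method:            voting ensemble
genes:             800  (P=20, NP=780)
features used:     25
train / val genes: 560 / 240
seed:              3
voting weights:    xgb=3, gb=2, ada=1, rf=4
----------------------------------------------------------
cross-validation (5 folds, mean +/- SD):
  MCC   0.3311 +/- 0.2180
  GM    0.7272 +/- 0.4132
  BA    0.8236 +/- 0.2107
  F1    0.2828 +/- 0.1711
held-out validation split:
  MCC   0.2266
  GM    0.6778
  F1    0.2143
  BA    0.7094
----------------------------------------------------------
top-ranked genes (pain score):
     1  G000018  0.9418
     2  G000015  0.9416
     3  G000016  0.9413
     4  G000028  0.9348
     5  G000010  0.9283
```

The held-out GM of 0.68 on this deliberately small 800-gene cohort
(only 20 positives) says the ensemble recovers planted signal well
above chance (a label-permuted null sits near 0.5); the low F1 is the
expected face of 1:40 imbalance — precision is paid for recall. The
top-ranked genes are dominated by planted positives and their
hub-neighbourhood analogues. Validating the ranking against the
cohort's synthetic external gene set:

```python
print(res.enrich([cohort.validation_set], n_perm=1000))
```

```
            set  n_hits       es   p_perm  n_hits_noleak  es_noleak  p_perm_noleak
synthetic_HPGDB      40 0.728947 0.000999             26   0.618962       0.000999
```

Enrichment survives removal of the training-labelled genes
(`es_noleak` = 0.62 at the permutation floor p ≈ 0.001), i.e. the
ranking generalizes beyond its labels.

The same pipeline runs from the shell:

```sh
painrank run --seed 3 --outdir out/          # full default cohort
painrank simulate --seed 3 --outdir cohort/  # just the synthetic data
```

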