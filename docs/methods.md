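# Methods

## The prioritization model

`painrank` scores genes for involvement in pain by supervised
classification on an engineered gene × feature matrix. The positive
(P) class is the small set of genes with gold-standard causal evidence;
everything else is labelled non-pain (NP), with the explicit
working assumption that undiscovered pain genes hide inside NP — which
is why the deliverable is a *ranking* by class-1 probability (the pain
score), not a hard label set.

The classifier is a weighted soft-voting ensemble of four tree
learners in fixed member order — XGBoost, gradient boosting, AdaBoost,
random forest. Class probabilities are weight-averaged and the hard
label is taken at threshold 0.5. Weights come from an exhaustive
permutation search of the multiset {4, 2, 1, 3} over the members,
maximizing the geometric mean (GM) of out-of-fold soft-vote
predictions; ties break by lexicographic enumeration order, so the
search is deterministic. A stacking alternative fits a logistic
regression on out-of-fold base probabilities.

### Why these metrics

At a ~1:40 class ratio, accuracy is uninformative. Model selection and
reporting use MCC, GM, F1 and balanced accuracy, computed from the
confusion matrix at threshold 0.5. Degenerate-margin conventions: MCC
is 0 when any marginal factor is 0; sensitivity or specificity with an
empty denominator is 0; F1 is 0 when precision + recall = 0. These keep
the metrics defined on sparse folds. Note that the chance level of GM
under a fixed 0.5 threshold is √(q(1−q)) where q is the classifier's
positive-prediction rate — at most 0.5, and far below it for a
conservative classifier; balanced training (below) keeps q near 1/2 so
that chance-level GM sits near 0.5 and the signal/null contrast is
interpretable.

### Imbalance handling

Each member trains on **all positives plus its own random negative
subsample of equal size** (`neg_pos_ratio = 1.0`), drawn
deterministically from the member's seed and position, with balanced
class weighting on top. Without undersampling, tree ensembles at 1:40
drive unseen-row probabilities toward 0 (most leaves are pure
negative), hard predictions collapse to the majority class, and GM is 0
regardless of ranking quality. Per-member subsampling restores a
meaningful 0.5 operating point and lets the four members jointly cover
~4× more of the negative class than any single one. The ratio is a
tunable: larger values trade recall for precision.

### Feature space

Per gene: three ordinal-coded categoricals (cellular compartment,
tissue of highest expression, chromosome; codes assigned by sorted
label order, unseen labels to a reserved code), GC content (%),
conservation score, GO1/GO2 (below), one composite LFC column per
(tissue, species) omics group (log2 units), TPM expression columns,
eleven PPI topology features, and a 0/1 flag for genes absent from the
graph. Missing numeric values impute to 0 ("not detected") before
scaling. Scaling is an affine map of each feature's *training-row*
range onto [−1, 1]; constant features map to 0; validation rows may
legitimately land outside [−1, 1].

**GO features.** Terms are filtered to prevalence < 20 % of the
training genes and any term whose identifier or name contains "pain"
(case-insensitive) is banned outright — such terms are near-synonyms of
the label and would leak it. Surviving terms are TF-IDF weighted
(smoothed IDF ln((1+N)/(1+df)) + 1, L2 row normalization) and projected
onto the first two principal components. Vocabulary, IDF and PCA basis
are all fitted on training genes only.

**Composite LFC.** Within each (tissue, species) group of
log-fold-change datasets, an entry is zeroed unless its paired FDR is
< 0.05 (missing FDR counts as non-significant), then the per-gene mean
over the group's datasets is taken. The result is invariant to dataset
order within the group.

**Correlation filter.** While any feature pair has |Pearson r| ≥ 0.75
(measured on training rows), the lower-variance member is dropped
(ties: the later column). Dropped names are logged in the matrix's
provenance record.

### Network topology

Eleven per-node features of the undirected PPI graph, following the
NetworkAnalyzer conventions for the nonstandard ones: stress counts
shortest paths through a node with each unordered endpoint pair counted
once; radiality is Σ(Δ+1−d(v,w))/(n−1) with Δ the component diameter;
the topological coefficient averages shared-neighbour counts (plus 1
for adjacency) over partners, divided by the node degree, and is 0 for
degree < 2. Path-based features are computed within connected
components ("noninfinite" convention) and betweenness is normalized by
the component's (n−1)(n−2)/2. Internally, distances, geodesic counts,
and the stress/betweenness dependency accumulations are vectorized over
BFS levels with sparse adjacency products (O(n·m) per component), so a
4,100-node scale-free graph takes ~20 s on one CPU.

### Feature attribution

Importance is **tree-path (Saabas) attribution**: walking a sample's
decision path, each split credits its feature with the change in node
expected output, so per-tree credits plus the root expectation
reconstruct the tree's output exactly. Ensembles combine per-tree
attributions the way they combine trees (forest: average in probability
space; boosting: learning-rate-weighted sum in margin space; AdaBoost:
estimator-weight average of stump probabilities — an additive surrogate
of its vote; XGBoost: the booster's native `approx_contribs`, same
semantics). Cross-learner combination normalizes the voting weights.
Since attribution drives a *ranking* (backward elimination, importance
tables), the mixed probability/margin scales across families are
harmless; additivity within each family is covered by tests. Backward
elimination drops the lowest mean-|attribution| feature per step,
re-measuring cross-validated GM/MCC, and returns the subset with the
best GM (MCC tie-break); a `refit` strategy (leave-one-out re-fitting
per step) is available behind a flag.

### Ranking validation

The pain-score ranking is validated by a classic unweighted
Kolmogorov–Smirnov running sum: +1/|hits| at set members, −1/|misses|
elsewhere; ES is the signed extremum (ties toward the positive
deviation). The null permutes set membership over the ranking universe
(there are no sample phenotypes to permute);
p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1) so p is never 0. A
score-weighted variant (exponent 1) exists behind a flag, but pain
scores are used only through their order, making exponent 0 the
natural default. Because validation sets can share members with the
training labels, every enrichment is reported twice — full set, and
set minus training positives ("leakage removed"). Decile
over-representation uses the hypergeometric upper tail per term with
Benjamini–Hochberg adjustment across terms, on the top or bottom
⌈10 %⌉ of the ranking.

## The synthetic cohort

No per-gene compiled dataset ships with the method, so the generator
(`painrank.simulate`) produces cohorts with the structure the analysis
assumes. Defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 4100 | cohort size |
| `pos_fraction` | 1/41 | P/NP = 1/40 → exactly 100 positives |
| `graph_attachment` | 3 | preferential-attachment edges per node |
| `hub_bias` | 2.0 | positives sampled ∝ degree^bias |
| `n_go_terms` / informative | 300 / 20 | GO vocabulary size |
| `go_enrichment_odds` | 4.0 | odds multiplier of informative terms in P |
| `n_omics_groups` × datasets | 6 × 2 | (tissue, species) LFC/FDR pairs |
| `lfc_effect` / `lfc_noise_sd` | 1.0 / 1.0 | log2 shift in carriers / noise |
| `frac_significant_background` | 0.05 | background FDR < 0.05 rate |
| `validation_overlap` | 0.5 | external-set fraction drawn from P |

Effect carriers are a random half of the positives per omics group,
emulating the observation that different datasets highlight different
genes. Carriers receive significant FDRs only when `lfc_effect` is
non-zero — a differential-expression analysis flags genes because their
expression actually changed — so disabling all effects yields a
genuinely exchangeable null cohort (held-out GM ≈ 0.5). Every cohort
carries a decoy GO term named "response to pain signal", strongly
label-correlated, existing solely so the tests can prove the
vocabulary guard excludes it. Gene identifiers are synthetic
(G000001…): no real gene symbols, no accidental biological claims. The
master seed fans out to the component simulators by fixed offsets.

**What the generator does not emulate:** expression covariance across
tissues, ortholog structure between species, annotation biases of real
GO, or the literature-driven correlations between network degree and
study attention. Passing tests therefore demonstrate that the pipeline
recovers the *kinds* of structure it assumes, at realistic sizes and
noise — not that any particular real gene list would be reproduced.

## Numerical and design choices

* Significance direction: entries are zeroed when FDR **≥** 0.05
  (significance at FDR < 0.05); correlation filtering triggers at
  |r| **≥** 0.75. Both interpretation notes are echoed in every run log.
* Probability threshold 0.5 wherever a confusion matrix is needed; the
  threshold is a parameter, not a tuned quantity.
* All stochastic components (learners, folds, subsampling, permutation
  nulls, the tuner) take explicit seeds; the library default seed is
  20240101, and the CLI threads one `--seed` through everything.
  Results are independent of thread count (all learners run
  single-threaded).
* Hyperparameter tuning is a pluggable contract: a seeded random search
  over a user-supplied grid optimizing the summed GM + MCC + BA + F1
  cross-validated objective. Any optimizer with the same signature can
  stand in.
* Ties in gene ranking break by gene identifier; ties in the weight
  search by lexicographic permutation order; |ES| ties toward the
  positive deviation (tolerance 1e-12).
* Cross-validation re-fits the ensemble per fold with the searched
  weights held fixed; re-running the permutation search inside each
  fold would multiply cost without changing the assessment.

## Problem sizes used by the test suite

Unit tests run on 120–800-gene cohorts and 6–12-node graphs with
brute-force oracles (explicit path enumeration, exhaustive permutation
and hypergeometric enumeration, hand-computed TF-IDF). The end-to-end
recovery checks run the full default 4,100-gene cohort across five
seeds against label-permuted null baselines; enrichment calibration
uses 200 replicates of 300-gene rankings with 500-permutation nulls.
The acceptance script runs one full default cohort with 10-fold
cross-validation per invocation.

## Known limitations

* Attribution is path-dependent (Saabas), not interventional Shapley;
  on deeply interacting features the two can rank differently.
  Additivity, not Shapley axioms, is the tested guarantee.
* AdaBoost attribution explains an additive surrogate (the
  estimator-weighted stump vote), not the exact SAMME probability
  transform.
* The stacking meta-model's attribution maps base-probability credit
  back through coefficient magnitudes — a chain-rule approximation.
* GM/MCC values on synthetic cohorts are not comparable to values
  reported on any real compiled dataset; the synthetic effect sizes
  are chosen to be realistic, not calibrated to a specific study.
* Normalized enrichment scores (NES) across set sizes are out of
  scope; comparisons across sets of very different sizes should use
  the permutation p-values.
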