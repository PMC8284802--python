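# Methods

## Problem and model

Given a genes × samples expression matrix with a sample → tissue
assignment and a global protein-interaction network, the package scores
every (gene, tissue) pair for tissue-functional relevance.  The score is
the positive-class probability of a gradient-boosted decision-tree
ensemble (XGBoost, `binary:logistic`) over 14 per-pair features, trained
on curated positive and negative pairs.

### Expression features (per gene, per tissue)

Over the tissue's samples *x*: `MeanExp = mean(x)`,
`MedianExp = median(x)`, `SDofExp = sd(x, ddof=1)`,
`CV = SDofExp / MeanExp` (missing when the mean is 0),
`MAD = median(|x_i − median(x)|)`,
`Breadth = #{i : x_i > median(x)} / n` (strict inequality; ties at the
median count as not-above), and `ZScore` = the mean over tissue samples
of the gene's pooled z-transform `(value − pooled mean)/(pooled SD)`
computed across all samples of all tissues.  Genes with zero pooled SD
get z = 0 everywhere and are logged.

Choices worth noting:

* **ddof = 1** for all standard deviations: the samples are individuals
  drawn from a population and the quantity of interest is
  inter-individual dispersion.  Configurable.
* **Breadth's reference median** is the median over the tissue's own
  samples by default, which makes Breadth concentrate near 0.5 for
  continuous data (its observed between-class means differ only in the
  tails); a pooled-across-tissues median is available via
  `breadth_median="pooled"`.
* No internal normalization or log transform: features are computed on
  the matrix as provided (normalized units such as TPM are assumed).

### Tissue network projection and network features

An edge {g1, g2} of the global network is retained in tissue *t* iff the
fraction of *t*'s samples in which **both** genes simultaneously exceed
their pooled (all-samples) median expression is ≥ 25% (`min_frac`).
This joint reading encodes within-tissue co-expression; a marginal
variant (each endpoint independently ≥ 25%) is selectable with
`rule="marginal"`.  Network genes absent from the expression matrix are
dropped with a logged count.

Per node: `Degree`; `Centrality_coeff` = betweenness centrality with
standard pair normalization (endpoints excluded, shortest-path
multiplicity weighted), computed exactly — at the graph sizes this
package targets (up to a few tens of thousands of nodes) exact
Brandes-style computation is feasible, though it dominates runtime on
large networks; `Clustering_coeff` = 2·(edges among neighbors)/(k(k−1)),
0 for degree < 2; kinase/TF neighbor counts from the supplied
membership sets; and neighbor means of ZScore and Breadth, averaged
over neighbors with defined values (isolated nodes get missing means).
Genes present in expression but absent from the tissue network carry
missing network features rather than zeros — absence from the network
is information, and the tree learner routes missing values natively.

### Gold set

(g, t) is **P** iff some disease maps to both t (disease–tissue
curation) and g (disease–gene curation).  Among the rest, (g, t) is
**N** iff the protein-detection table marks g undetected in t; pairs
absent from the detection table stay **U**.  When a disease-linked pair
is also undetected, P wins and the conflict is logged: curated positive
evidence is stronger than absence of detection.  The three labels
partition the universe; the classifier trains on P vs N only.

### Classifier and evaluation regimes

Defaults: `max_depth=3`, `positive_class_weight=10` (implemented as
`scale_pos_weight`, equivalent to a 10× misclassification penalty on
positives), `n_folds=5`, `n_repeats=100`, `n_trees=100`,
`learning_rate=0.1`.  Tree count and learning rate are this package's
own defaults, recorded in every output manifest and sidecar.  Training
is single-threaded and deterministic given the seed.

* **Repeated CV**: "n repeats of stratified 5-fold CV"; repeat *r* seeds
  fold assignment with `seed + r`; each repeat pools its out-of-fold
  predictions into one auROC and one auPRC, and the reported metric is
  the mean ± SD over repeats.
* **Group leave-one-out by gene**: a labeled pair's unbiased score comes
  from a model refit with *all* pairs of that gene excluded, preventing
  leakage across tissues of the same gene.  Unlabeled pairs are scored
  by the single full model (a CV-bagged average would also be defensible;
  the full model is simpler and deterministic).
* **Leave-one-tissue-out**: a tissue's genes are scored by a model never
  shown any of that tissue's rows.

Normalized rank within a tissue: average-tie rank of the score divided
by the number of scored genes, in (0, 1] with 1 = best.

Feature importance is the split count ("F score") per feature, reported
for all 14 features including zeros.

### Evaluation statistics

auROC uses the Mann–Whitney identity (ties counted ½); auPRC is
step-integrated precision over recall, whose chance level equals the
positive prevalence.  Wilcoxon tests are two-sample rank-sum for class
comparisons and signed-rank for paired rank comparisons; exact
enumeration below 25 observations per group, normal approximation with
tie/continuity correction above; two-sided unless a direction is part
of the claim (positives ranked *higher*).  Per-feature discrimination
reports the rank-sum p, auROC/auPRC using the raw feature as the score
(orientation flipped so auROC ≥ 0.5), class means and the
positive/negative mean ratio; constant features report p = 1,
auROC = 0.5.  No multiple-testing correction is applied to per-tissue
tests by default.

The Z-score-matched negative subsampling control bins the positives'
ZScore into 20 equal-mass quantile bins and draws, per bin and without
replacement, as many negatives as there are positives; empty bins are
skipped with a warning and reported as shortfall.  Matching can only
reduce or preserve the KS distance between the two distributions.

### Downstream statistics

* **Top fraction**: the ⌈frac·n⌉ highest-scoring genes of a tissue, ties
  at the cutoff broken by gene id (10% for enrichment, 5% for
  clustering analyses).
* **Trait mapping**: a gene links to a trait iff it harbors a SNP with
  association p < 1e-10 inside its [start, end) locus; traits need ≥ 5
  linked genes.  Enrichment is a two-sided Fisher exact test of the 2×2
  overlap table, sample odds ratio (a·d)/(b·c); a trait "passes" at
  OR > 1.5 and p < 0.05.  The universe is the set of scored genes in
  the tissue.
* **Linear clustering**: within a gene set G, per chromosome, maximal
  runs of consecutive G-members whose successive *start* coordinates
  differ by ≤ 500 kb and holding ≥ 5 (alternatively 3) members; the
  statistic is the fraction of G covered by such runs.  Distance is
  start-to-start because gene starts are the single anchor every
  annotation provides; end-to-start is a config alternative.
  "Consecutive" means consecutive within G, not within the whole
  annotation, matching the fraction-of-G statistic.
* **TAD coverage**: a gene belongs to the TAD containing its start
  (TADs must be non-overlapping); the statistic counts TADs holding
  ≥ `min_genes_per_tad` members of G.  With `min_genes_per_tad=1`
  ("TADs covering all genes of G") tighter packing gives *fewer* TADs
  and the lower tail indicates clustering; with the default 2 the count
  instead *rises* under clustering, so significance claims in this
  package's own analyses use 1.  Both are exposed because the two
  definitions circulate and give opposite directions.
* **Permutation null**: 1000 random gene sets of the same size and the
  same per-chromosome composition drawn from the annotated universe;
  z = (observed − null mean)/null SD and the add-one empirical
  p = (1 + hits)/(1 + draws), which can never be 0 at finite draws.
  When the null is a point mass equal to the observation, z = 0;
  when it is a point mass away from it, z = ±inf.  For calibration
  studies an optional smoothed estimator breaks observed-null ties
  uniformly at random, making p exactly uniform under the null despite
  the statistic's discreteness; reported p-values always use the
  conservative add-one form.
* **Tissue dendrogram**: per tissue the top-20 scoring transcription
  factors; distance = 1 − Jaccard of the two sets; Ward linkage applied
  to the condensed distance matrix itself (the Jaccard distances are the
  quantity of interest; embedding them in a Euclidean space first would
  change them), exported as Newick.

## Synthetic studies

`fugue.simulate.generate_study` draws a complete study from one seed:

* **Expression**: log-normal, gene-level baseline log-mean ~ N(2, 1),
  within-gene log SD 0.5; values below the 5th percentile are zeroed so
  Breadth and the edge rule see zero inflation.  Defaults: 5 tissues ×
  20 samples, 400 genes.
* **Planted positives** (20 per tissue, disjoint across tissues): in
  their tissue, +2 within-gene SD mean log shift and within-tissue SD
  halved (`cv_ratio=0.5`) — reproducing the observed effect directions:
  higher mean/median/Z-score, lower CV.
* **Network**: sparse random background (mean degree 4) plus 10 extra
  edges per positive, preferentially to TF/kinase nodes (10% TFs, 5%
  kinases), planting hubness and regulator-neighbor signal.
* **Genome**: 5 chromosomes, inter-gene start gaps uniform on
  50–200 kb (gene-dense spacing, so random sets occasionally form runs
  and the clustering null is non-degenerate); 10 of tissue 1's
  positives placed contiguously within 2 Mb; TADs tile each chromosome
  in 1 Mb windows.
* **Labels**: planted positives are P; 200 random non-positive genes
  per tissue are N (prevalence 20/220 ≈ 0.09, matching the strong
  curation imbalance); the rest U.  Curation tables (disease–tissue,
  disease–gene, detection) are emitted that reproduce exactly these
  labels through the gold-set assembly path.
* **Trait and DEG sets**: 20 genes each, half drawn from a tissue's
  positives.

What the generator does **not** emulate: realistic marginal expression
distributions or correlation structure, scale-free interactome
topology, chromosome-length heterogeneity, or label noise in curation.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's computations and the recoverability of effects of the
planted kind — not expected performance on real tissue atlases, where
the reported effects are far weaker and partially confounded.

## Problem sizes

The test suite and the acceptance script run at 400 genes × 5 tissues ×
100 samples (2,000 gene-tissue pairs, 1,100 labeled; the permuted-label
calibration uses a 2,000-labeled-pair variant), 10–20 CV repeats, and
100–1000 permutation resamples.  These sizes give stable statistics
(CV metric SDs < 0.01; null z estimates from 1000 draws) while keeping
a full run in tens of seconds on one CPU.

## Known limitations

* Exact betweenness is O(V·E) per tissue; on interactome-scale graphs
  (~15k nodes, ~300k edges) expect minutes per tissue.
* Leave-one-out by gene refits one model per labeled gene; use it for
  final unbiased scores, not for exploration.
* The classifier's probabilities are uncalibrated (class weighting
  shifts them upward); ranks within a tissue are the intended output.
* Tissues with zero positives are scored but excluded from rank tests;
  gold-set assembly allows them by design.
* The Fisher odds ratio is the sample (a·d)/(b·c), reported as +inf
  with a flag when a zero cell makes it undefined; the conditional MLE
  variant is not used.
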