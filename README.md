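# fugue — prioritizing tissue-relevant genes

FUGUE scores every (gene, tissue) pair for its likely relevance to the
tissue's function by combining two kinds of evidence that a plain
tissue-specificity ranking ignores:

* **Expression features** over a tissue's samples — mean and median
  expression, sample standard deviation, coefficient of variation
  (CV = SD/mean), median absolute deviation from the median (MADM),
  expression *breadth* (the fraction of the tissue's samples in which the
  gene exceeds its median expression), and the mean *Z-score* (the gene's
  expression standardized across all samples of all tissues, averaged
  over the tissue's samples).
* **Network features** from a tissue-projected protein-interaction
  network — degree, betweenness centrality, local clustering
  coefficient, counts of kinase and transcription-factor neighbors, and
  neighbor means of Z-score and breadth.  An interactome edge survives
  in a tissue when both endpoint genes exceed their pooled median
  expression simultaneously in at least 25% of the tissue's samples.

The 14 features feed a gradient-boosted decision-tree classifier
(XGBoost; depth-3 trees, logistic loss, positive class weighted 10×
against the ~0.1 positive:negative imbalance) trained on a curated gold
set: positives are (gene, tissue) pairs linked through disease–tissue
and disease–gene curation, negatives are pairs whose protein is never
detected in the tissue, everything else is unlabeled.  Scores are
evaluated by repeated stratified 5-fold cross-validation, by per-gene
group leave-one-out, and by leave-one-tissue-out scoring; the top-ranked
genes per tissue are then tested for trait enrichment (Fisher exact
test), linear genomic clustering (runs of ≥ 5 genes within 500 kb,
chromosome-matched permutation null), TAD co-localization, and
regulator-overlap tissue dendrograms (1 − Jaccard of top-20 TFs, Ward
linkage).

Intended users: computational biologists with a multi-sample expression
matrix (e.g. TPM), a protein-interaction edge list, and curation tables,
who want per-tissue gene rankings that go beyond the Z-score.

## Worked example

Everything below runs on a synthetic study with planted tissue-relevant
genes, generated by the package itself:

```sh
fugue simulate --seed 17 --out study/
fugue run-all --study-dir study/ --seed 17 --out out/
```

`run-all` prints the cross-validation summary from the run manifest:

```
{
  "auprc_mean": 0.9891818181818179,
  "auprc_sd": 0.00402326484193034,
  "auroc_mean": 0.99405,
  "auroc_sd": 0.002212795663061697
}
outputs -> out/
```

With the default planted effects (positives shifted +2 SD in log
expression in their tissue, halved CV, 10 extra interactome edges) the
classifier separates positive from negative pairs almost perfectly;
under permuted labels the same cross-validation returns an auPRC equal
to the 0.09 positive prevalence, the chance level.  `out/` contains the
feature table, labels, the score table (gene, tissue, label, score,
normalized rank), per-feature discrimination statistics, per-tissue rank
tests, trait/DEG enrichment, genomic and TAD clustering statistics with
z-scores and empirical p-values, and a Newick tissue dendrogram.

The same steps are available individually (`fugue features`, `labels`,
`train`, `cv`, `score`, `loto`, `evaluate`, `enrich`, `clusters`,
`tads`, `dendrogram`), or from Python:

```python
from fugue import compute_feature_table, ModelParams, repeated_cv
from fugue.simulate import SimConfig, generate_study

study = generate_study(SimConfig(seed=17))
features = compute_feature_table(study.expression, study.network, study.flags)
cv = repeated_cv(features, study.labels, ModelParams(n_repeats=10, seed=17))
print(cv[["auroc", "auprc"]].mean())
```

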