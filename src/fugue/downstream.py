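"""Post-scoring analyses of the top-ranked genes.

* Fisher trait-tissue enrichment of GWAS-linked genes among a tissue's
  top-scoring genes (odds ratio > 1.5 and p < 0.05 call a trait).
* Linear genomic clustering: the fraction of a gene set covered by runs
  of >= ``min_genes`` consecutive set members whose successive start
  coordinates are <= ``max_gap`` apart, against a chromosome-matched
  permutation null (z > 0 indicates clustering).
* TAD co-localization: the number of topologically associating domains
  holding >= ``min_genes_per_tad`` set members, against the same null
  (z < 0 indicates clustering).
* Tissue similarity from regulators: 1 - Jaccard distance between
  tissues' top-k transcription-factor sets, Ward-linkage tree, Newick.

Empirical p-values use the add-one estimator (1 + hits) / (1 + draws),
so they are never zero at finite resampling depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from fugue.data_io import DataError, GeneAnnotation, TadSet

logger = logging.getLogger(__name__)


def select_top_fraction(score_table: pd.DataFrame, tissue: str, frac: float) -> list[str]:
    """The ceil(frac * n) highest-scoring genes of a tissue.

    Ties at the cutoff break deterministically by gene id.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    grp = score_table[score_table["tissue"] == tissue]
    if grp.empty:
        raise DataError(f"tissue {tissue!r} not scored")
    k = int(np.ceil(frac * len(grp)))
    ordered = grp.sort_values(["score", "gene"], ascending=[False, True])
    return ordered["gene"].head(k).tolist()


def map_snps_to_genes(
    snp_table: pd.DataFrame,
    ann: GeneAnnotation,
    p_max: float = 1e-10,
    min_genes: int = 5,
) -> dict[str, set[str]]:
    """Link traits to genes via intragenic genome-wide-significant SNPs.

    ``snp_table`` columns: chrom, pos (0-based), p, trait.  A gene is
    linked to a trait iff it harbors a SNP with p < ``p_max`` inside its
    [start, end) locus.  Traits with fewer than ``min_genes`` linked
    genes are dropped.
    """
    sig = snp_table[snp_table["p"] < p_max]
    out: dict[str, set[str]] = {}
    tbl = ann.table
    for trait, grp in sig.groupby("trait"):
        genes: set[str] = set()
        for chrom, chrom_snps in grp.groupby("chrom"):
            genes_here = tbl[tbl["chrom"] == chrom]
            pos = chrom_snps["pos"].to_numpy()
            for gene_id, row in genes_here.iterrows():
                if ((pos >= row["start"]) & (pos < row["end"])).any():
                    genes.add(gene_id)
        if len(genes) >= min_genes:
            out[str(trait)] = genes
    return out


@dataclass
class EnrichmentResult:
    """2x2 Fisher overlap of a query set with a target set in a universe."""

    name: str
    tissue: str
    a: int  # in query and target
    b: int  # in query only
    c: int  # in target only
    d: int  # in neither
    odds_ratio: float
    fisher_p: float
    passed: bool


def set_enrichment(
    query: set[str],
    target: set[str],
    universe: set[str],
    or_min: float = 1.5,
    p_max: float = 0.05,
    name: str = "",
    tissue: str = "",
) -> EnrichmentResult:
    """Fisher exact test of overlap between two gene sets in a universe.

    The odds ratio is the sample (a*d)/(b*c); a zero denominator with a
    nonzero numerator reports +inf.  ``passed`` requires both
    odds_ratio > or_min and two-sided p < p_max.
    """
    if not universe:
        raise DataError("empty universe")
    q, t = query & universe, target & universe
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsr = np.inf if a * d > 0 else np.nan
        if not np.isfinite(oddsr):
            logger.info("enrichment %s/%s: zero-cell odds ratio", name, tissue)
    else:
        oddsr = (a * d) / (b * c)
    passed = bool(np.isfinite(p) and p < p_max and (oddsr > or_min))
    return EnrichmentResult(
        name=name, tissue=tissue, a=a, b=b, c=c, d=d,
        odds_ratio=float(oddsr), fisher_p=float(p), passed=passed,
    )


# ---------------------------------------------------------------------------
# linear genomic clustering


def genomic_clusters(
    genes, ann: GeneAnnotation, min_genes: int = 5, max_gap: int = 500_000
) -> tuple[list[list[str]], float]:
    """Runs of nearby set members on the genome and the fraction covered.

    Per chromosome, the members of the gene set are ordered by start
    coordinate; maximal runs where successive starts differ by <=
    ``max_gap`` and holding >= ``min_genes`` members are clusters.
    Returns (clusters, f) with f = (genes inside clusters) / |set|.
    Unannotated genes are dropped with a logged count.
    """
    genes = set(genes)
    annotated = [g for g in genes if g in ann.table.index]
    n_dropped = len(genes) - len(annotated)
    if n_dropped:
        logger.info("genomic_clusters: %d unannotated gene(s) dropped", n_dropped)
    if not annotated:
        return [], 0.0
    sub = ann.table.loc[annotated].sort_values(["chrom", "start"])
    clusters: list[list[str]] = []
    for _, grp in sub.groupby("chrom", sort=False):
        ids = grp.index.tolist()
        starts = grp["start"].to_numpy()
        run = [ids[0]]
        for i in range(1, len(ids)):
            if starts[i] - starts[i - 1] <= max_gap:
                run.append(ids[i])
            else:
                if len(run) >= min_genes:
                    clusters.append(run)
                run = [ids[i]]
        if len(run) >= min_genes:
            clusters.append(run)
    covered = sum(len(c) for c in clusters)
    return clusters, covered / len(annotated)


@dataclass
class ClusterStatResult:
    """Observed statistic against a permutation null."""

    kind: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_resamples: int


def permutation_null(
    statistic_fn,
    genes,
    ann: GeneAnnotation,
    n_resamples: int = 1000,
    seed: int = 0,
    chromosome_matched: bool = True,
    tail: str = "upper",
    kind: str = "fraction_in_clusters",
    tie_break_random: bool = False,
) -> ClusterStatResult:
    """Compare a gene-set statistic against random sets from the annotation.

    Random sets have the same size as the observed set and, when
    ``chromosome_matched``, the same per-chromosome gene counts.  The
    empirical p-value is add-one corrected: (1 + hits) / (1 + draws),
    with hits counted in the requested tail (upper: null >= observed).

    ``tie_break_random`` counts null draws exactly tied with the observed
    value as hits with probability 1/2 each (smoothed permutation p).
    Under the null this makes the p-value exactly uniform despite the
    statistic's discreteness; use it for calibration studies, not for
    reporting (the default conservative estimator never understates
    significance).
    """
    rng = np.random.default_rng(seed)
    genes = [g for g in genes if g in ann.table.index]
    if not genes:
        raise DataError("no annotated genes in the observed set")
    observed = float(statistic_fn(genes))
    universe = ann.table
    null_vals = np.empty(n_resamples)
    if chromosome_matched:
        per_chrom = universe.loc[genes, "chrom"].value_counts()
        pools = {
            chrom: universe.index[universe["chrom"] == chrom].to_numpy()
            for chrom in per_chrom.index
        }
        for chrom, k in per_chrom.items():
            if k > len(pools[chrom]):
                raise DataError(f"{chrom}: requested {k} genes, only {len(pools[chrom])} annotated")
        for i in range(n_resamples):
            draw: list[str] = []
            for chrom, k in per_chrom.items():
                draw.extend(rng.choice(pools[chrom], size=k, replace=False))
            null_vals[i] = statistic_fn(draw)
    else:
        pool = universe.index.to_numpy()
        for i in range(n_resamples):
            null_vals[i] = statistic_fn(rng.choice(pool, size=len(genes), replace=False))
    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1))
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
    elif observed == null_mean:
        z = 0.0  # point-mass null, no deviation
    else:
        z = np.inf if observed > null_mean else -np.inf
    if tail == "upper":
        strict = int((null_vals > observed).sum())
    elif tail == "lower":
        strict = int((null_vals < observed).sum())
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    ties = int((null_vals == observed).sum())
    if tie_break_random:
        # smoothed permutation p: exactly Uniform(0,1) under the null
        p = (strict + rng.uniform() * (ties + 1)) / (1 + n_resamples)
    else:
        p = (1 + strict + ties) / (1 + n_resamples)
    return ClusterStatResult(
        kind=kind, observed=observed, null_mean=null_mean, null_sd=null_sd,
        z=float(z), empirical_p=float(p), n_resamples=n_resamples,
    )


def genomic_cluster_test(
    genes, ann: GeneAnnotation, min_genes: int = 5, max_gap: int = 500_000,
    n_resamples: int = 1000, seed: int = 0,
) -> ClusterStatResult:
    """Permutation test of the fraction-in-clusters statistic (upper tail)."""
    return permutation_null(
        lambda g: genomic_clusters(g, ann, min_genes=min_genes, max_gap=max_gap)[1],
        genes, ann, n_resamples=n_resamples, seed=seed,
        tail="upper", kind="fraction_in_clusters",
    )


# ---------------------------------------------------------------------------
# TAD coverage


def tad_coverage(
    genes, tads: TadSet, ann: GeneAnnotation, min_genes_per_tad: int = 2
) -> tuple[int, int]:
    """(number of TADs holding >= min_genes_per_tad set members, uncovered genes).

    A gene belongs to the TAD containing its start coordinate (TADs are
    non-overlapping, so the assignment is unique).  A smaller TAD count
    for a fixed set size indicates tighter spatial packing.
    """
    genes = [g for g in genes if g in ann.table.index]
    counts: dict[int, int] = {}
    n_uncovered = 0
    iv = tads.intervals
    for g in genes:
        row = ann.table.loc[g]
        hit = iv[
            (iv["chrom"] == row["chrom"])
            & (iv["start"] <= row["start"])
            & (row["start"] < iv["end"])
        ]
        if hit.empty:
            n_uncovered += 1
        else:
            t = int(hit.index[0])
            counts[t] = counts.get(t, 0) + 1
    n_tads = sum(1 for v in counts.values() if v >= min_genes_per_tad)
    return n_tads, n_uncovered


def tad_coverage_test(
    genes, tads: TadSet, ann: GeneAnnotation, min_genes_per_tad: int = 2,
    n_resamples: int = 1000, seed: int = 0,
) -> ClusterStatResult:
    """Permutation test of the TAD count (lower tail: fewer TADs = clustered)."""
    return permutation_null(
        lambda g: tad_coverage(g, tads, ann, min_genes_per_tad=min_genes_per_tad)[0],
        genes, ann, n_resamples=n_resamples, seed=seed,
        tail="lower", kind="n_tads",
    )


# ---------------------------------------------------------------------------
# regulator-overlap tissue dendrogram


@dataclass
class TissueDistanceMatrix:
    """Pairwise 1 - Jaccard distances of tissues' top-k TF sets + Ward tree."""

    tissues: list[str]
    distances: pd.DataFrame
    linkage: np.ndarray
    top_sets: dict[str, set[str]]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        return _newick(tree, self.tissues) + ";"


def _newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _newick(node.get_left(), names)
    right = _newick(node.get_right(), names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def tissue_tf_dendrogram(
    score_table: pd.DataFrame, tf_set: set[str], top_k: int = 20
) -> TissueDistanceMatrix:
    """Cluster tissues by overlap of their top-k scoring transcription factors.

    Per tissue the top-k TFs by score (ties by gene id); distance between
    tissues = 1 - |intersection| / |union| of the two sets; Ward linkage
    on the condensed distance matrix.  Tissues with fewer than ``top_k``
    scored TFs use all available (logged).
    """
    tissues = sorted(score_table["tissue"].unique())
    top_sets: dict[str, set[str]] = {}
    for tissue in tissues:
        grp = score_table[
            (score_table["tissue"] == tissue) & score_table["gene"].isin(tf_set)
        ]
        if len(grp) < top_k:
            logger.info(
                "dendrogram: tissue %s has %d scored TFs (< %d); using all",
                tissue, len(grp), top_k,
            )
        ordered = grp.sort_values(["score", "gene"], ascending=[False, True])
        top_sets[tissue] = set(ordered["gene"].head(top_k))
    n = len(tissues)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = top_sets[tissues[i]], top_sets[tissues[j]]
            union = len(a | b)
            jac = len(a & b) / union if union else 1.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    condensed = dist[np.triu_indices(n, k=1)]
    link = hierarchy.ward(condensed)
    return TissueDistanceMatrix(
        tissues=tissues,
        distances=pd.DataFrame(dist, index=tissues, columns=tissues),
        linkage=link,
        top_sets=top_sets,
    )
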