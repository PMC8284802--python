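"""Synthetic multi-tissue studies with planted tissue-relevant genes.

The generator emulates every input the pipeline consumes: a log-normal
expression matrix over tissues and samples, a random interactome, TF and
kinase memberships, a gene annotation with a planted linear cluster, a
TAD tiling, gold-set curation tables, trait gene sets, and cancer DEG
lists.  Planted positives reproduce the effect directions the method
exploits: elevated and stable expression in their tissue (positive mean
log shift, reduced within-tissue dispersion), network hubness (extra
edges, preferentially to regulators), and genomic co-location for a
subset.  Every draw flows from one seed; identical configs yield
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from fugue.data_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneClassFlags,
    GlobalNetwork,
    TadSet,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    ``z_shift`` is the mean log-expression shift of a positive gene in
    its tissue, in units of the within-gene log SD (~2 pooled SDs at the
    default dispersion); ``cv_ratio`` multiplies the within-tissue SD of
    positives (< 1 = more stable expression); ``hub_boost`` adds that
    many extra interactome edges per positive, preferentially to TF or
    kinase nodes.  Defaults give ~0.09 positive prevalence among labeled
    pairs, matching a strongly imbalanced curation.
    """

    n_tissues: int = 5
    samples_per_tissue: int = 20
    n_genes: int = 400
    n_positive_per_tissue: int = 20
    n_negative_per_tissue: int = 200
    z_shift: float = 2.0
    cv_ratio: float = 0.5
    hub_boost: int = 10
    fraction_tf: float = 0.10
    fraction_kinase: float = 0.05
    n_clustered_positives: int = 10
    cluster_span_bp: int = 2_000_000
    tad_size_bp: int = 1_000_000
    n_chromosomes: int = 5
    mean_degree: float = 4.0
    base_log_sd: float = 0.5
    zero_quantile: float = 0.05
    trait_size: int = 20
    trait_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cv_ratio <= 1:
            raise ValueError("cv_ratio must be in (0, 1]")
        if self.n_positive_per_tissue * self.n_tissues > self.n_genes:
            raise ValueError("more planted positives than genes")
        if self.n_clustered_positives > self.n_positive_per_tissue:
            raise ValueError("n_clustered_positives exceeds positives per tissue")
        per_chrom = self.n_genes // self.n_chromosomes
        if self.n_clustered_positives > per_chrom:
            raise ValueError("clustered positives do not fit on one chromosome")


@dataclass
class SyntheticStudy:
    """Everything the pipeline reads, plus the planted ground truth."""

    expression: ExpressionMatrix
    network: GlobalNetwork
    flags: GeneClassFlags
    annotation: GeneAnnotation
    tads: TadSet
    labels: pd.DataFrame  # gene, tissue, label over the full universe
    positives: dict[str, list[str]]  # tissue -> planted positive genes
    clustered_genes: list[str]
    trait_sets: dict[str, set[str]]
    deg_sets: dict[str, set[str]]
    disease_tissue: pd.DataFrame
    disease_gene: pd.DataFrame
    detection: pd.DataFrame = field(repr=False)


def generate_study(cfg: SimConfig) -> SyntheticStudy:
    """Draw one complete synthetic study from the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tissues = [f"T{t + 1}" for t in range(cfg.n_tissues)]

    # planted positives: disjoint blocks of genes per tissue
    shuffled = list(rng.permutation(genes))
    positives: dict[str, list[str]] = {}
    cursor = 0
    for t in tissues:
        positives[t] = sorted(shuffled[cursor : cursor + cfg.n_positive_per_tissue])
        cursor += cfg.n_positive_per_tissue
    pos_of: dict[str, str] = {g: t for t, gs in positives.items() for g in gs}

    # regulator classes
    n_tf = int(round(cfg.fraction_tf * cfg.n_genes))
    n_kin = int(round(cfg.fraction_kinase * cfg.n_genes))
    reg_pick = list(rng.permutation(genes))
    tfs = frozenset(reg_pick[:n_tf])
    kinases = frozenset(reg_pick[n_tf : n_tf + n_kin])
    flags = GeneClassFlags(tfs=tfs, kinases=kinases)

    # expression: log-normal with gene-level baselines; positives get a
    # +z_shift*sigma mean shift and cv_ratio-scaled noise in their tissue
    samples = [f"{t}_s{i:02d}" for t in tissues for i in range(cfg.samples_per_tissue)]
    sample_tissue = pd.Series(
        [s.split("_s")[0] for s in samples], index=pd.Index(samples, name="sample")
    )
    mu = rng.normal(2.0, 1.0, size=cfg.n_genes)
    sigma = cfg.base_log_sd
    logx = np.empty((cfg.n_genes, len(samples)))
    for j, s in enumerate(samples):
        t = sample_tissue.iloc[j]
        eps = rng.normal(0.0, 1.0, size=cfg.n_genes)
        shift = np.zeros(cfg.n_genes)
        scale = np.full(cfg.n_genes, sigma)
        for i, g in enumerate(genes):
            if pos_of.get(g) == t:
                shift[i] = cfg.z_shift * sigma
                scale[i] = sigma * cfg.cv_ratio
        logx[:, j] = mu + shift + scale * eps
    x = np.exp(logx)
    if cfg.zero_quantile > 0:
        cut = np.quantile(x, cfg.zero_quantile)
        x = np.where(x < cut, 0.0, x)
    expression = ExpressionMatrix(
        values=pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples),
        sample_tissue=sample_tissue,
    )

    # interactome: sparse random background + hub edges for positives
    p_edge = cfg.mean_degree / (cfg.n_genes - 1)
    g = nx.fast_gnp_random_graph(
        cfg.n_genes, p_edge, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    regulators = sorted(tfs | kinases)
    for gene in sorted(pos_of):
        for _ in range(cfg.hub_boost):
            if regulators and rng.random() < 0.7:
                other = regulators[rng.integers(len(regulators))]
            else:
                other = genes[rng.integers(cfg.n_genes)]
            if other != gene:
                g.add_edge(gene, other)
    network = GlobalNetwork(graph=g)

    # annotation: genes spread over chromosomes with wide gaps, except a
    # planted contiguous block of tissue-1 positives within cluster_span_bp
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    clustered = positives[tissues[0]][: cfg.n_clustered_positives]
    rest = [gn for gn in genes if gn not in clustered]
    rng.shuffle(rest)
    chrom_genes: dict[str, list[str]] = {}
    cursor = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_here = per_chrom if c < cfg.n_chromosomes - 1 else cfg.n_genes - cursor - len(
            clustered if c == 0 else []
        )
        if c == 0:
            take = per_chrom - len(clustered)
            order = rest[cursor : cursor + take]
            cursor += take
            insert_at = int(rng.integers(len(order) + 1))
            order = order[:insert_at] + clustered + order[insert_at:]
        else:
            order = rest[cursor : cursor + n_here]
            cursor += n_here
        chrom_genes[chrom] = order
    rows = []
    tight_gap = cfg.cluster_span_bp // max(cfg.n_clustered_positives - 1, 1)
    for chrom, order in chrom_genes.items():
        pos = int(rng.integers(100_000, 300_000))
        for i, gene in enumerate(order):
            length = int(rng.integers(10_000, 100_000))
            rows.append((gene, chrom, pos, pos + length, "+"))
            if i + 1 < len(order):
                nxt = order[i + 1]
                if gene in clustered and nxt in clustered:
                    gap = tight_gap
                else:
                    gap = int(rng.integers(50_000, 200_000))
                pos += gap
    ann_df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    annotation = GeneAnnotation(table=ann_df)

    # TADs: non-overlapping tiling of each chromosome
    tad_rows = []
    for chrom, grp in ann_df.groupby("chrom"):
        top = int(grp["end"].max()) + cfg.tad_size_bp
        for s in range(0, top, cfg.tad_size_bp):
            tad_rows.append((chrom, s, s + cfg.tad_size_bp))
    tads = TadSet(intervals=pd.DataFrame(tad_rows, columns=["chrom", "start", "end"]))

    # labels over the full universe; negatives sampled from non-positives
    label_rows = []
    negatives: dict[str, list[str]] = {}
    for t in tissues:
        non_pos = [gn for gn in genes if pos_of.get(gn) != t]
        negatives[t] = sorted(
            rng.choice(non_pos, size=cfg.n_negative_per_tissue, replace=False)
        )
    for t in tissues:
        neg = set(negatives[t])
        for gn in genes:
            if pos_of.get(gn) == t:
                lab = "P"
            elif gn in neg:
                lab = "N"
            else:
                lab = "U"
            label_rows.append((gn, t, lab))
    labels = pd.DataFrame(label_rows, columns=["gene", "tissue", "label"])

    # gold-set curation tables consistent with the planted labels
    disease_tissue = pd.DataFrame(
        {"disease": [f"d_{t}" for t in tissues], "tissue": tissues}
    )
    disease_gene = pd.DataFrame(
        [(f"d_{t}", gn) for t in tissues for gn in positives[t]],
        columns=["disease", "gene"],
    )
    detection = pd.DataFrame(True, index=pd.Index(genes, name="gene"), columns=tissues)
    for t in tissues:
        detection.loc[negatives[t], t] = False

    # trait gene sets overlapping each tissue's positives; DEG up/down lists
    trait_sets: dict[str, set[str]] = {}
    for t in tissues:
        n_hit = int(round(cfg.trait_overlap * cfg.trait_size))
        hits = list(rng.choice(positives[t], size=min(n_hit, len(positives[t])), replace=False))
        others = [gn for gn in genes if pos_of.get(gn) != t]
        fill = list(rng.choice(others, size=cfg.trait_size - len(hits), replace=False))
        trait_sets[f"trait_{t}"] = set(hits) | set(fill)
    t1 = tissues[0]
    up_hits = list(rng.choice(positives[t1], size=cfg.n_positive_per_tissue // 2, replace=False))
    others = [gn for gn in genes if pos_of.get(gn) != t1]
    deg_sets = {
        "DEG_up": set(up_hits)
        | set(rng.choice(others, size=cfg.trait_size, replace=False)),
        "DEG_down": set(rng.choice(others, size=cfg.trait_size, replace=False)),
    }

    return SyntheticStudy(
        expression=expression,
        network=network,
        flags=flags,
        annotation=annotation,
        tads=tads,
        labels=labels,
        positives=positives,
        clustered_genes=clustered,
        trait_sets=trait_sets,
        deg_sets=deg_sets,
        disease_tissue=disease_tissue,
        disease_gene=disease_gene,
        detection=detection,
    )


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Serialize a study into the pipeline's on-disk input formats.

    Writes expression.tsv, tissue_map.tsv, network.tsv, flags.gmt,
    genes.bed, tads.bed, disease_tissue.tsv, disease_gene.tsv,
    detection.tsv, labels.tsv, traits.gmt and degs.gmt; returns a
    name -> path map.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[os.path.splitext(name)[0]] = path = os.path.join(outdir, name)
        return path

    study.expression.values.to_csv(p("expression.tsv"), sep="\t", lineterminator="\n")
    study.expression.sample_tissue.to_csv(
        p("tissue_map.tsv"), sep="\t", header=False, lineterminator="\n"
    )
    with open(p("network.tsv"), "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in study.network.graph.edges):
            fh.write(f"{u}\t{v}\n")
    with open(p("flags.gmt"), "w") as fh:
        fh.write("TF\tsynthetic\t" + "\t".join(sorted(study.flags.tfs)) + "\n")
        fh.write("Kinase\tsynthetic\t" + "\t".join(sorted(study.flags.kinases)) + "\n")
    ann = study.annotation.table.reset_index()
    ann[["chrom", "start", "end", "gene_id", "strand"]].assign(score=0)[
        ["chrom", "start", "end", "gene_id", "score", "strand"]
    ].to_csv(p("genes.bed"), sep="\t", header=False, index=False, lineterminator="\n")
    study.tads.intervals.to_csv(
        p("tads.bed"), sep="\t", header=False, index=False, lineterminator="\n"
    )
    study.disease_tissue.to_csv(p("disease_tissue.tsv"), sep="\t", index=False, lineterminator="\n")
    study.disease_gene.to_csv(p("disease_gene.tsv"), sep="\t", index=False, lineterminator="\n")
    study.detection.to_csv(p("detection.tsv"), sep="\t", lineterminator="\n")
    study.labels.to_csv(p("labels.tsv"), sep="\t", index=False, lineterminator="\n")
    with open(p("traits.gmt"), "w") as fh:
        for name, members in sorted(study.trait_sets.items()):
            fh.write(f"{name}\tsynthetic\t" + "\t".join(sorted(members)) + "\n")
    with open(p("degs.gmt"), "w") as fh:
        for name, members in sorted(study.deg_sets.items()):
            fh.write(f"{name}\tsynthetic\t" + "\t".join(sorted(members)) + "\n")
    return paths
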