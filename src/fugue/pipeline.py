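"""End-to-end orchestration: features -> labels -> model -> evaluation -> downstream.

A run is driven by one :class:`RunConfig` (loadable from YAML).  All
randomness flows from the single root seed through named per-stage
substreams, so a config + seed pair reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from fugue import __version__
from fugue.data_io import (
    read_bed,
    read_class_flags,
    read_edge_list,
    read_expression,
    read_gmt,
    write_scores,
)
from fugue.downstream import (
    genomic_cluster_test,
    select_top_fraction,
    set_enrichment,
    tad_coverage_test,
    tissue_tf_dendrogram,
)
from fugue.evaluation import compare_to_zscore_baseline, feature_discrimination, rank_tests
from fugue.features import compute_feature_table
from fugue.gold_set import assemble_gold_set
from fugue.model import ModelParams, cv_summary, loo_pair_scores, repeated_cv, score_all

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Paths, model parameters and thresholds for one pipeline run."""

    expression: str = "expression.tsv"
    tissue_map: str = "tissue_map.tsv"
    network: str = "network.tsv"
    flags: str = "flags.gmt"
    genes_bed: str = "genes.bed"
    tads_bed: str = "tads.bed"
    disease_tissue: str = "disease_tissue.tsv"
    disease_gene: str = "disease_gene.tsv"
    detection: str = "detection.tsv"
    traits_gmt: str = "traits.gmt"
    degs_gmt: str = "degs.gmt"
    model: ModelParams = field(default_factory=ModelParams)
    scoring: str = "full"  # 'full' or 'loo'
    top_frac: float = 0.10
    cluster_top_frac: float = 0.05
    or_min: float = 1.5
    p_max: float = 0.05
    cluster_min_genes: int = 5
    max_gap: int = 500_000
    min_genes_per_tad: int = 2
    top_k_tf: int = 20
    n_resamples: int = 1000
    seed: int = 0
    outdir: str = "fugue_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = ModelParams(**raw.pop("model", {}))
        return cls(model=model, **raw)

    def resolve(self, base: str) -> "RunConfig":
        """Interpret relative input paths against a base directory."""
        cfg = RunConfig(**{**asdict(self), "model": self.model})
        for name in (
            "expression", "tissue_map", "network", "flags", "genes_bed",
            "tads_bed", "disease_tissue", "disease_gene", "detection",
            "traits_gmt", "degs_gmt",
        ):
            p = getattr(cfg, name)
            if p and not os.path.isabs(p):
                setattr(cfg, name, os.path.join(base, p))
        return cfg


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise PipelineError(f"stage {stage!r}: missing input {path}")
    return path


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> str:
    """Execute every stage and write the output tree; returns the outdir."""
    os.makedirs(cfg.outdir, exist_ok=True)
    params = ModelParams(**{**asdict(cfg.model), "seed": cfg.seed})

    # --- inputs
    E = read_expression(
        _require(cfg.expression, "inputs"), _require(cfg.tissue_map, "inputs")
    )
    net = read_edge_list(_require(cfg.network, "inputs"))
    flags = read_class_flags(_require(cfg.flags, "inputs"))
    ann = read_bed(_require(cfg.genes_bed, "inputs"), kind="genes")
    tads = read_bed(_require(cfg.tads_bed, "inputs"), kind="tads")

    # --- features
    try:
        features = compute_feature_table(E, net, flags)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError(f"stage 'features': {e}") from e
    features.to_csv(
        os.path.join(cfg.outdir, "features.tsv"), sep="\t", index=False, lineterminator="\n"
    )

    # --- labels
    universe = features[["gene", "tissue"]].drop_duplicates()
    detection = pd.read_csv(_require(cfg.detection, "labels"), sep="\t", index_col=0)
    labels = assemble_gold_set(
        pd.read_csv(_require(cfg.disease_tissue, "labels"), sep="\t"),
        pd.read_csv(_require(cfg.disease_gene, "labels"), sep="\t"),
        detection.astype(bool),
        universe,
    )
    labels.to_csv(
        os.path.join(cfg.outdir, "labels.tsv"), sep="\t", index=False, lineterminator="\n"
    )

    # --- scoring
    if cfg.scoring == "loo":
        scores = loo_pair_scores(features, labels, params)
    else:
        scores = score_all(features, labels, params)
    write_scores(scores, os.path.join(cfg.outdir, "scores.tsv"))

    # --- evaluation
    cv = repeated_cv(features, labels, params)
    cv.to_csv(os.path.join(cfg.outdir, "cv_repeats.tsv"), sep="\t", index=False, lineterminator="\n")
    disc = feature_discrimination(features, labels)
    disc.to_csv(
        os.path.join(cfg.outdir, "feature_discrimination.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    ranks = rank_tests(scores)
    ranks["per_tissue"].to_csv(
        os.path.join(cfg.outdir, "rank_tests_per_tissue.tsv"),
        sep="\t", index=False, lineterminator="\n",
    )
    baseline = compare_to_zscore_baseline(scores, features)
    baseline.to_csv(
        os.path.join(cfg.outdir, "zscore_baseline.tsv"), sep="\t", index=False, lineterminator="\n"
    )

    # --- downstream
    tissues = sorted(scores["tissue"].unique())
    trait_sets = read_gmt(cfg.traits_gmt) if os.path.exists(cfg.traits_gmt) else {}
    deg_sets = read_gmt(cfg.degs_gmt) if os.path.exists(cfg.degs_gmt) else {}
    enrich_rows = []
    for tissue in tissues:
        uni = set(scores.loc[scores["tissue"] == tissue, "gene"])
        top = set(select_top_fraction(scores, tissue, cfg.top_frac))
        for name, members in {**trait_sets, **deg_sets}.items():
            r = set_enrichment(
                top, members & uni, uni, or_min=cfg.or_min, p_max=cfg.p_max,
                name=name, tissue=tissue,
            )
            enrich_rows.append(r.__dict__)
    pd.DataFrame(enrich_rows).to_csv(
        os.path.join(cfg.outdir, "enrichment.tsv"), sep="\t", index=False, lineterminator="\n"
    )

    cluster_rows = []
    for tissue in tissues:
        top5 = select_top_fraction(scores, tissue, cfg.cluster_top_frac)
        lin = genomic_cluster_test(
            top5, ann, min_genes=cfg.cluster_min_genes, max_gap=cfg.max_gap,
            n_resamples=cfg.n_resamples, seed=cfg.seed + 1,
        )
        tad = tad_coverage_test(
            top5, tads, ann, min_genes_per_tad=cfg.min_genes_per_tad,
            n_resamples=cfg.n_resamples, seed=cfg.seed + 2,
        )
        for res in (lin, tad):
            cluster_rows.append({"tissue": tissue, **res.__dict__})
    pd.DataFrame(cluster_rows).to_csv(
        os.path.join(cfg.outdir, "clustering.tsv"), sep="\t", index=False, lineterminator="\n"
    )

    if flags.tfs:
        dend = tissue_tf_dendrogram(scores, set(flags.tfs), top_k=cfg.top_k_tf)
        with open(os.path.join(cfg.outdir, "tissue_dendrogram.nwk"), "w") as fh:
            fh.write(dend.to_newick() + "\n")
        dend.distances.to_csv(
            os.path.join(cfg.outdir, "tissue_distances.tsv"), sep="\t", lineterminator="\n"
        )

    # --- manifest
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "model_params": asdict(params),
        "cv_summary": cv_summary(cv),
        "n_pairs": int(len(features)),
        "n_tissues": len(tissues),
    }
    with open(os.path.join(cfg.outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cfg.outdir
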