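"""Tissue projection of the global interactome and network features.

An edge of the global protein-interaction network survives in a tissue if
both endpoint genes are expressed above their pooled median (across all
samples of all tissues) simultaneously in at least a fraction ``min_frac``
(default 25%) of that tissue's samples.  The joint reading — both genes
above their medians in the same samples — encodes co-expression within the
tissue; a marginal variant (each gene independently) is selectable.

Seven features are computed on the projected network per node: degree,
betweenness centrality (pair-normalized, exact), local clustering
coefficient, counts of kinase and TF neighbors, and the neighbor means of
the expression ZScore and Breadth features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from fugue.data_io import DataError, ExpressionMatrix, GeneClassFlags, GlobalNetwork

logger = logging.getLogger(__name__)

NETWORK_FEATURES = [
    "Degree",
    "Centrality_coeff",
    "Clustering_coeff",
    "NumOfKinaseNbs",
    "NumOfTFNeighbors",
    "NeighborMeanZscore",
    "NeighborMeanBreadth",
]


@dataclass
class TissueNetwork:
    """Subgraph of the global network surviving one tissue's expression filter."""

    tissue: str
    graph: nx.Graph


def build_tissue_network(
    E: ExpressionMatrix,
    net: GlobalNetwork,
    tissue: str,
    min_frac: float = 0.25,
    rule: str = "joint",
) -> TissueNetwork:
    """Project the global network into a tissue.

    rule='joint': an edge {g1, g2} is retained iff the fraction of tissue
    samples in which g1 and g2 are simultaneously above their pooled
    medians is >= min_frac.  rule='marginal': each endpoint must exceed
    its pooled median in >= min_frac of tissue samples independently.

    Network genes absent from the expression matrix are dropped (logged).
    """
    samples = E.tissue_samples(tissue)
    genes_in_net = [g for g in net.graph.nodes if g in E.values.index]
    dropped = net.graph.number_of_nodes() - len(genes_in_net)
    if dropped:
        logger.info(
            "%s: %d network gene(s) absent from expression matrix dropped",
            tissue, dropped,
        )
    pooled_median = E.values.median(axis=1)
    sub = E.values.loc[genes_in_net, samples]
    above = sub.gt(pooled_median.loc[genes_in_net], axis=0)  # genes x samples bool
    n = len(samples)
    g = nx.Graph()
    g.add_nodes_from(genes_in_net)
    above_arr = above.to_numpy()
    idx = {gene: i for i, gene in enumerate(genes_in_net)}
    for u, v in net.graph.edges:
        if u not in idx or v not in idx:
            continue
        au, av = above_arr[idx[u]], above_arr[idx[v]]
        if rule == "joint":
            ok = (au & av).sum() / n >= min_frac
        elif rule == "marginal":
            ok = au.sum() / n >= min_frac and av.sum() / n >= min_frac
        else:
            raise ValueError(f"rule must be 'joint' or 'marginal', got {rule!r}")
        if ok:
            g.add_edge(u, v)
    return TissueNetwork(tissue=tissue, graph=g)


def topology_features(tn: TissueNetwork) -> pd.DataFrame:
    """Degree, betweenness centrality and clustering coefficient per node.

    Betweenness uses the standard pair normalization (endpoints excluded,
    shortest-path multiplicity weighted), computed exactly.  Clustering is
    2 * (edges among neighbors) / (k * (k - 1)), 0 for degree < 2.
    """
    g = tn.graph
    if g.number_of_nodes() == 0:
        raise DataError(f"empty tissue network for {tn.tissue!r}")
    degree = dict(g.degree)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    clustering = nx.clustering(g)
    return pd.DataFrame(
        {
            "Degree": pd.Series(degree, dtype=float),
            "Centrality_coeff": pd.Series(betweenness),
            "Clustering_coeff": pd.Series(clustering, dtype=float),
        }
    )


def neighbor_features(
    tn: TissueNetwork,
    flags: GeneClassFlags,
    expr_features: pd.DataFrame,
) -> pd.DataFrame:
    """Typed-neighbor counts and neighbor means of ZScore and Breadth.

    ``expr_features`` is the per-gene expression feature frame for the same
    tissue (indexed by gene id).  Neighbor means average over neighbors
    with a defined value; isolated nodes get counts 0 and NaN means.
    """
    g = tn.graph
    z = expr_features["ZScore"]
    b = expr_features["Breadth"]
    rows = {}
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        zvals = z.reindex(nbrs).dropna()
        bvals = b.reindex(nbrs).dropna()
        rows[node] = (
            sum(flags.is_kinase(n) for n in nbrs),
            sum(flags.is_tf(n) for n in nbrs),
            zvals.mean() if len(zvals) else np.nan,
            bvals.mean() if len(bvals) else np.nan,
        )
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=[
            "NumOfKinaseNbs",
            "NumOfTFNeighbors",
            "NeighborMeanZscore",
            "NeighborMeanBreadth",
        ],
    )


def network_feature_table(
    tn: TissueNetwork, flags: GeneClassFlags, expr_features: pd.DataFrame
) -> pd.DataFrame:
    """All seven network features for one tissue, indexed by gene id."""
    topo = topology_features(tn)
    nbr = neighbor_features(tn, flags, expr_features)
    return topo.join(nbr)[NETWORK_FEATURES]
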