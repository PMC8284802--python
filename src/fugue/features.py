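"""Assembly of the full 14-column (gene, tissue) feature table."""

from __future__ import annotations

import pandas as pd

from fugue.data_io import ExpressionMatrix, GeneClassFlags, GlobalNetwork
from fugue.expression_features import (
    EXPRESSION_FEATURES,
    pooled_zscore,
    tissue_expression_features,
)
from fugue.tissue_network import (
    NETWORK_FEATURES,
    build_tissue_network,
    network_feature_table,
)

FEATURE_COLUMNS = EXPRESSION_FEATURES + NETWORK_FEATURES


def compute_feature_table(
    E: ExpressionMatrix,
    net: GlobalNetwork,
    flags: GeneClassFlags,
    tissues: list[str] | None = None,
    min_frac: float = 0.25,
    edge_rule: str = "joint",
    breadth_median: str = "tissue",
) -> pd.DataFrame:
    """Compute all 14 features for every (gene, tissue) pair.

    Genes present in the expression matrix but absent from the tissue
    network carry NaN network features (absence from the network is
    signal, not zero).  Returns a long DataFrame with columns
    gene, tissue, and FEATURE_COLUMNS.
    """
    if tissues is None:
        tissues = E.tissues
    z = pooled_zscore(E)
    frames = []
    for tissue in tissues:
        expr = tissue_expression_features(
            E, tissue, breadth_median=breadth_median, zscores=z
        )
        tn = build_tissue_network(E, net, tissue, min_frac=min_frac, rule=edge_rule)
        netf = network_feature_table(tn, flags, expr)
        merged = expr.join(netf.reindex(expr.index))
        merged = merged.reset_index(names="gene")
        merged.insert(1, "tissue", tissue)
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)
    return out[["gene", "tissue"] + FEATURE_COLUMNS]
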