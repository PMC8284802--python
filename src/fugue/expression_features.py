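"""Per-(gene, tissue) expression features.

Seven summaries of a gene's expression over the samples of one tissue:
central tendency (MeanExp, MedianExp), dispersion (SDofExp, CV, MAD),
robustness across individuals (Breadth), and tissue specificity (ZScore,
the mean over tissue samples of the gene's expression standardized across
all samples of all tissues).

Dispersion uses the sample standard deviation (ddof=1): the quantity of
interest is inter-individual variability, estimated from a sample of
individuals.  Missing values (CV at zero mean) are emitted as NaN; the
downstream tree model routes missing values natively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fugue.data_io import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

EXPRESSION_FEATURES = [
    "MeanExp",
    "MedianExp",
    "SDofExp",
    "CV",
    "MAD",
    "Breadth",
    "ZScore",
]


def pooled_zscore(E: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Standardize each gene's expression across all samples of all tissues.

    Returns a genes x samples DataFrame of z values.  Genes with zero
    pooled standard deviation get z = 0 everywhere (logged); they carry no
    specificity signal in any tissue.
    """
    v = E.values
    if v.shape[1] < 2:
        raise DataError("z-transform needs at least 2 samples")
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        logger.info("%d gene(s) with zero pooled SD; z set to 0", int(flat.sum()))
    z = v.sub(mean, axis=0).div(sd.where(~flat, np.inf), axis=0)
    return z


def tissue_expression_features(
    E: ExpressionMatrix,
    tissue: str,
    breadth_median: str = "tissue",
    ddof: int = 1,
    zscores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute the seven expression features for every gene in one tissue.

    Parameters
    ----------
    breadth_median
        ``'tissue'`` (default): Breadth counts tissue samples exceeding the
        gene's median over that tissue's samples; ``'pooled'`` uses the
        gene's median over all samples instead.
    zscores
        Precomputed :func:`pooled_zscore` output, to avoid recomputation
        when iterating over tissues.

    Returns a DataFrame indexed by gene id with EXPRESSION_FEATURES columns.
    Breadth uses a strict inequality, so ties at the median count as
    not-above.  CV is NaN where the tissue mean is 0.
    """
    samples = E.tissue_samples(tissue)
    if len(samples) < 2:
        raise DataError(f"tissue {tissue!r} has fewer than 2 samples")
    x = E.values[samples]
    mean = x.mean(axis=1)
    median = x.median(axis=1)
    sd = x.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (sd / mean).where(mean > 0)
    mad = x.sub(median, axis=0).abs().median(axis=1)
    ref = median if breadth_median == "tissue" else E.values.median(axis=1)
    breadth = x.gt(ref, axis=0).sum(axis=1) / len(samples)
    if zscores is None:
        zscores = pooled_zscore(E, ddof=ddof)
    zmean = zscores[samples].mean(axis=1)
    return pd.DataFrame(
        {
            "MeanExp": mean,
            "MedianExp": median,
            "SDofExp": sd,
            "CV": cv,
            "MAD": mad,
            "Breadth": breadth,
            "ZScore": zmean,
        }
    )


def expression_feature_table(
    E: ExpressionMatrix, breadth_median: str = "tissue", ddof: int = 1
) -> pd.DataFrame:
    """All expression features for every (gene, tissue) pair.

    Returns a long DataFrame with columns gene, tissue and the seven
    feature columns, ordered by tissue then gene id.
    """
    z = pooled_zscore(E, ddof=ddof)
    frames = []
    for tissue in E.tissues:
        f = tissue_expression_features(
            E, tissue, breadth_median=breadth_median, ddof=ddof, zscores=z
        )
        f = f.reset_index(names="gene")
        f.insert(1, "tissue", tissue)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
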