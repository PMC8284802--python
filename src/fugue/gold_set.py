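"""Gold-set curation: positive / negative / unlabeled (gene, tissue) labels.

A pair (g, t) is Positive when some disease is curated both to tissue t
and to gene g.  Among the remaining pairs, those whose protein is not
detected in the tissue are Negative; everything else stays Unlabeled.
Positive evidence (disease curation) takes precedence over
absence-of-detection when the two rules conflict; conflicts are logged.
"""

from __future__ import annotations

import logging

import pandas as pd

from fugue.data_io import DataError

logger = logging.getLogger(__name__)

LABELS = ("P", "N", "U")


def assemble_gold_set(
    disease_tissue: pd.DataFrame,
    disease_gene: pd.DataFrame,
    detection: pd.DataFrame,
    universe: pd.DataFrame,
) -> pd.DataFrame:
    """Label every (gene, tissue) pair of the universe as P, N or U.

    Parameters
    ----------
    disease_tissue
        Two columns, disease and tissue.
    disease_gene
        Two columns, disease and gene.
    detection
        Boolean genes x tissues protein-detection matrix (index gene id);
        False means the protein was never detected in the tissue.  Pairs
        absent from the matrix stay Unlabeled.
    universe
        Two columns, gene and tissue: all pairs to label.

    Returns the universe with a ``label`` column.  P and N partition with
    U: every pair receives exactly one label.
    """
    if len(universe) == 0:
        raise DataError("empty (gene, tissue) universe")
    universe = universe[["gene", "tissue"]].drop_duplicates()
    known_tissues = set(universe["tissue"])
    extra = set(disease_tissue.iloc[:, 1]) - known_tissues
    if extra:
        raise DataError(f"disease map names unknown tissues: {sorted(extra)[:5]}")

    dt = disease_tissue.iloc[:, :2].set_axis(["disease", "tissue"], axis=1)
    dg = disease_gene.iloc[:, :2].set_axis(["disease", "gene"], axis=1)
    positives = dt.merge(dg, on="disease")[["gene", "tissue"]].drop_duplicates()
    pos_idx = pd.MultiIndex.from_frame(positives)

    uni_idx = pd.MultiIndex.from_frame(universe)
    is_pos = uni_idx.isin(pos_idx)

    det_long = detection.stack()
    undetected = set(det_long.index[~det_long.astype(bool)])
    is_undet = pd.Series(
        [pair in undetected for pair in zip(universe["gene"], universe["tissue"])],
        index=universe.index,
    )

    conflicts = int((is_pos & is_undet.to_numpy()).sum())
    if conflicts:
        logger.info(
            "%d disease-linked but protein-undetected pair(s) kept Positive",
            conflicts,
        )

    label = pd.Series("U", index=universe.index)
    label[is_undet.to_numpy()] = "N"
    label[is_pos] = "P"
    out = universe.copy()
    out["label"] = label
    return out.reset_index(drop=True)


def partition_counts(n_total: int, n_positive: int, n_negative: int) -> dict[str, float]:
    """Derived counts of the P/N/U partition of a (gene, tissue) universe.

    Because the three labels partition the universe, the unlabeled count
    is the remainder, and the prevalence seen by the classifier (trained
    on P vs N only) is P / (P + N).
    """
    if n_positive + n_negative > n_total:
        raise ValueError("labeled pairs exceed the universe")
    n_unlabeled = n_total - n_positive - n_negative
    return {
        "n_unlabeled": n_unlabeled,
        "n_unlabeled_default": n_total - n_positive,  # before detection labels N
        "prevalence": n_positive / (n_positive + n_negative),
    }
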