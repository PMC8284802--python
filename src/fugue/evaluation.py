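"""Evaluation statistics for scores and individual features.

auROC is the Mann-Whitney probability of concordance (ties count 1/2);
auPRC is step-integrated precision over recall (average precision), whose
random-classifier expectation equals the positive prevalence.  Wilcoxon
tests are rank-sum (two-sample) or signed-rank (paired), exact for small
samples and normal-approximated with continuity/tie correction otherwise,
two-sided unless a direction is stated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from fugue.data_io import DataError

logger = logging.getLogger(__name__)


def auroc_auprc(scores, labels) -> tuple[float, float]:
    """Area under the ROC and precision-recall curves.

    ``labels`` are 0/1 (or 'P'/'N'); both classes must be present.
    """
    y = np.asarray([1 if v in (1, "P", True) else 0 for v in labels])
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("both classes required for auROC/auPRC")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def _ranksum_p(pos: np.ndarray, neg: np.ndarray, alternative: str = "two-sided") -> float:
    """Two-sample Wilcoxon rank-sum p; exact when small and tie-free."""
    if np.ptp(np.concatenate([pos, neg])) == 0:
        return 1.0
    method = "exact" if (len(pos) <= 25 and len(neg) <= 25) else "asymptotic"
    try:
        res = stats.mannwhitneyu(pos, neg, alternative=alternative, method=method)
    except ValueError:
        res = stats.mannwhitneyu(pos, neg, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


@dataclass
class DiscriminationRow:
    """Single-feature discrimination between positive and negative pairs."""

    feature: str
    wilcoxon_p: float
    auroc: float
    auprc: float
    neg_mean: float
    pos_mean: float
    effect_size: float  # pos_mean / neg_mean; NaN when neg_mean == 0


def feature_discrimination(features: pd.DataFrame, labels: pd.DataFrame,
                           feature_columns: list[str] | None = None) -> pd.DataFrame:
    """Score each feature alone as a classifier of P vs N pairs.

    For every feature: two-sided rank-sum p-value, auROC/auPRC using the
    raw feature values as scores (orientation flipped when needed so that
    auROC >= 0.5), class means and the pos/neg mean ratio.  Rows with a
    missing feature value are dropped per feature.
    """
    from fugue.features import FEATURE_COLUMNS

    cols = feature_columns if feature_columns is not None else FEATURE_COLUMNS
    merged = features.merge(labels[["gene", "tissue", "label"]], on=["gene", "tissue"])
    pn = merged[merged["label"].isin(["P", "N"])]
    rows = []
    for feat in cols:
        sub = pn[[feat, "label"]].dropna()
        pos = sub.loc[sub["label"] == "P", feat].to_numpy(dtype=float)
        neg = sub.loc[sub["label"] == "N", feat].to_numpy(dtype=float)
        if len(pos) == 0 or len(neg) == 0:
            raise DataError(f"feature {feat!r}: a class has no defined values")
        y = (sub["label"] == "P").to_numpy(dtype=int)
        s = sub[feat].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            p, auroc = 1.0, 0.5
            auprc = y.mean()
        else:
            p = _ranksum_p(pos, neg)
            auroc = roc_auc_score(y, s)
            if auroc < 0.5:
                s = -s
                auroc = roc_auc_score(y, s)
            auprc = average_precision_score(y, s)
        neg_mean, pos_mean = float(neg.mean()), float(pos.mean())
        rows.append(
            DiscriminationRow(
                feature=feat,
                wilcoxon_p=float(p),
                auroc=float(auroc),
                auprc=float(auprc),
                neg_mean=neg_mean,
                pos_mean=pos_mean,
                effect_size=pos_mean / neg_mean if neg_mean != 0 else np.nan,
            ).__dict__
        )
    return pd.DataFrame(rows)


def rank_tests(score_table: pd.DataFrame, alternative: str = "greater") -> dict:
    """Rank-based discrimination per tissue and per gene.

    Per tissue: rank-sum test of positives' vs negatives' normalized
    ranks (one-sided, positives higher, by default).  Per gene (genes
    with >= 1 positive and >= 1 negative tissue): the difference of the
    gene's mean rank in positive vs negative tissues, pooled across genes
    with a paired signed-rank test.  Tissues or genes lacking both
    classes are skipped with a log entry.
    """
    per_tissue = []
    for tissue, grp in score_table.groupby("tissue"):
        pos = grp.loc[grp["label"] == "P", "normalized_rank"].to_numpy()
        neg = grp.loc[grp["label"] == "N", "normalized_rank"].to_numpy()
        if len(pos) == 0 or len(neg) == 0:
            logger.info("rank_tests: tissue %s lacks both classes; skipped", tissue)
            continue
        per_tissue.append(
            {
                "tissue": tissue,
                "n_pos": len(pos),
                "n_neg": len(neg),
                "pos_mean_rank": float(pos.mean()),
                "neg_mean_rank": float(neg.mean()),
                "p": _ranksum_p(pos, neg, alternative=alternative),
            }
        )
    per_gene = []
    for gene, grp in score_table.groupby("gene"):
        pos = grp.loc[grp["label"] == "P", "normalized_rank"].to_numpy()
        neg = grp.loc[grp["label"] == "N", "normalized_rank"].to_numpy()
        if len(pos) == 0 or len(neg) == 0:
            continue
        per_gene.append(
            {"gene": gene, "diff": float(pos.mean() - neg.mean())}
        )
    per_gene_df = pd.DataFrame(per_gene, columns=["gene", "diff"])
    if len(per_gene_df) >= 2 and np.ptp(per_gene_df["diff"]) + abs(per_gene_df["diff"]).max() > 0:
        nonzero = per_gene_df["diff"].to_numpy()
        if np.any(nonzero != 0):
            pooled_p = float(
                stats.wilcoxon(nonzero, alternative=alternative).pvalue
            )
        else:
            pooled_p = 1.0
    else:
        pooled_p = np.nan
    return {
        "per_tissue": pd.DataFrame(per_tissue),
        "per_gene": per_gene_df,
        "pooled_gene_p": pooled_p,
    }


def zscore_matched_subsample(
    negatives: pd.DataFrame,
    positives: pd.DataFrame,
    feature: str = "ZScore",
    n_bins: int = 20,
    seed: int = 0,
) -> dict:
    """Subsample negatives so a feature's distribution matches the positives'.

    Bin edges are the positives' quantiles (``n_bins`` equal-mass bins);
    from each bin as many negatives are drawn without replacement as there
    are positives in it.  Bins with positive mass but no negatives are
    skipped with a warning and reported as shortfall.

    Returns ``{'indices', 'bin_histogram', 'shortfall'}`` where indices
    index into ``negatives``.
    """
    rng = np.random.default_rng(seed)
    pvals = positives[feature].dropna().to_numpy(dtype=float)
    nser = negatives[feature].dropna()
    edges = np.quantile(pvals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    pos_bins = np.clip(np.searchsorted(edges, pvals, side="right") - 1, 0, n_bins - 1)
    neg_bins = np.clip(
        np.searchsorted(edges, nser.to_numpy(dtype=float), side="right") - 1,
        0, n_bins - 1,
    )
    chosen: list = []
    histogram = {}
    shortfall = 0
    for b in range(n_bins):
        want = int((pos_bins == b).sum())
        if want == 0:
            continue
        avail = nser.index[neg_bins == b]
        if len(avail) == 0:
            logger.warning("matched subsample: bin %d empty among negatives", b)
            shortfall += want
            histogram[b] = 0
            continue
        take = min(want, len(avail))
        if take < want:
            shortfall += want - take
        chosen.extend(rng.choice(avail, size=take, replace=False).tolist())
        histogram[b] = take
    return {"indices": chosen, "bin_histogram": histogram, "shortfall": shortfall}


def compare_to_zscore_baseline(score_table: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Per tissue, do positives rank better by model score than by ZScore?

    Both orderings are converted to normalized ranks within the tissue;
    a paired signed-rank test on the positives' ranks gives a p-value and
    a direction (+1: model ranks higher on average, -1: ZScore does).
    Tissues with fewer than 2 positives are skipped.
    """
    merged = score_table.merge(
        features[["gene", "tissue", "ZScore"]], on=["gene", "tissue"]
    )
    rows = []
    for tissue, grp in merged.groupby("tissue"):
        n = len(grp)
        model_rank = grp["score"].rank(method="average") / n
        z_rank = grp["ZScore"].rank(method="average") / n
        pos = grp["label"] == "P"
        if pos.sum() < 2:
            logger.info("baseline comparison: tissue %s has < 2 positives; skipped", tissue)
            continue
        d = (model_rank[pos] - z_rank[pos]).to_numpy()
        if np.all(d == 0):
            p, direction = 1.0, 0
        else:
            p = float(stats.wilcoxon(d).pvalue)
            direction = int(np.sign(d.mean()))
        rows.append(
            {
                "tissue": tissue,
                "n_pos": int(pos.sum()),
                "mean_rank_diff": float(d.mean()),
                "direction": direction,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
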