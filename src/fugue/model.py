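"""The gene-tissue relevance classifier.

A gradient-boosted decision-tree ensemble (XGBoost) predicts the
probability that a (gene, tissue) pair is tissue-relevant from the 14
expression and network features.  Trees are shallow (max depth 3, logistic
loss) to resist overfitting under multicollinear features, and positive
misclassification is penalized 10x to counter the ~0.1 positive:negative
ratio.  Missing feature values (e.g. a gene absent from the tissue
network) are routed natively by the tree learner, never imputed.

Three scoring regimes avoid leakage:

* ``repeated_cv`` — stratified 5-fold cross-validation repeated over
  independent fold seeds; reports per-repeat fold-pooled auROC/auPRC.
* ``loo_pair_scores`` — each labeled pair is scored by a model trained
  with *all* pairs of that gene held out (group leave-one-out by gene);
  unlabeled pairs are scored by the full model.
* ``leave_one_tissue_out`` — a whole tissue is scored by a model never
  shown that tissue's rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from fugue.data_io import DataError
from fugue.features import FEATURE_COLUMNS


@dataclass
class ModelParams:
    """Hyperparameters of the boosted-tree classifier.

    ``positive_class_weight`` scales the logistic loss of positive
    instances (10 = positive misclassification penalized 10x).
    ``n_repeats`` counts independent repeats of the n-fold CV; repeat r
    uses ``seed + r`` for fold assignment.
    """

    max_depth: int = 3
    positive_class_weight: float = 10.0
    n_folds: int = 5
    n_repeats: int = 100
    n_trees: int = 100
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.positive_class_weight <= 0:
            raise ValueError("positive_class_weight must be > 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _classifier(params: ModelParams, seed: int) -> XGBClassifier:
    return XGBClassifier(
        max_depth=params.max_depth,
        n_estimators=params.n_trees,
        learning_rate=params.learning_rate,
        objective="binary:logistic",
        scale_pos_weight=params.positive_class_weight,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


def _labeled_xy(features: pd.DataFrame, labels: pd.DataFrame):
    """Join features with labels, keep P/N rows, return (frame, X, y)."""
    merged = features.merge(labels[["gene", "tissue", "label"]], on=["gene", "tissue"], how="left")
    merged["label"] = merged["label"].fillna("U")
    pn = merged[merged["label"].isin(["P", "N"])].reset_index(drop=True)
    X = pn[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = (pn["label"] == "P").to_numpy(dtype=int)
    return merged, pn, X, y


def train(features: pd.DataFrame, labels: pd.DataFrame, params: ModelParams) -> XGBClassifier:
    """Fit the classifier on the labeled (P vs N) pairs.

    ``features`` carries gene, tissue and the 14 feature columns;
    ``labels`` carries gene, tissue, label.  Deterministic given
    ``params.seed``.
    """
    _, pn, X, y = _labeled_xy(features, labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("training needs at least one positive and one negative pair")
    clf = _classifier(params, params.seed)
    clf.fit(X, y)
    return clf


def predict_scores(model: XGBClassifier, features: pd.DataFrame) -> pd.Series:
    """Probability of tissue relevance for every row of a feature table."""
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    return pd.Series(model.predict_proba(X)[:, 1], index=features.index, name="score")


def repeated_cv(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    params: ModelParams,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV on the labeled pairs.

    Each repeat pools the out-of-fold predictions of its ``n_folds`` folds
    and computes one auROC and one auPRC.  Returns one row per repeat with
    columns repeat, auroc, auprc.
    """
    _, pn, X, y = _labeled_xy(features, labels)
    if y.sum() < params.n_folds or (len(y) - y.sum()) < params.n_folds:
        raise DataError("a class is too small to stratify into folds")
    rows = []
    for r in range(params.n_repeats):
        rep_seed = params.seed + r
        skf = StratifiedKFold(n_splits=params.n_folds, shuffle=True, random_state=rep_seed)
        oof = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            clf = _classifier(params, rep_seed)
            clf.fit(X[train_idx], y[train_idx])
            oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
        rows.append(
            {
                "repeat": r,
                "auroc": roc_auc_score(y, oof),
                "auprc": average_precision_score(y, oof),
            }
        )
    return pd.DataFrame(rows)


def cv_summary(cv: pd.DataFrame) -> dict[str, float]:
    """Mean and SD over repeats of the CV metrics."""
    return {
        "auroc_mean": float(cv["auroc"].mean()),
        "auroc_sd": float(cv["auroc"].std(ddof=1)) if len(cv) > 1 else 0.0,
        "auprc_mean": float(cv["auprc"].mean()),
        "auprc_sd": float(cv["auprc"].std(ddof=1)) if len(cv) > 1 else 0.0,
    }


def make_score_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Attach within-tissue normalized ranks to a scored frame.

    Expects columns gene, tissue, label, score.  The normalized rank of a
    gene is (number of genes in the tissue with score <= its score) /
    (genes scored in the tissue), average ranks for ties; 1 = best.
    """
    out = scored[["gene", "tissue", "label", "score"]].copy()
    out["normalized_rank"] = (
        out.groupby("tissue")["score"].rank(method="average", ascending=True)
        / out.groupby("tissue")["score"].transform("size")
    )
    return out


def score_all(
    features: pd.DataFrame, labels: pd.DataFrame, params: ModelParams
) -> pd.DataFrame:
    """Score every (gene, tissue) pair with one full model; add ranks."""
    model = train(features, labels, params)
    merged, _, _, _ = _labeled_xy(features, labels)
    merged["score"] = predict_scores(model, merged)
    return make_score_table(merged)


def loo_pair_scores(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    params: ModelParams,
    group_by: str = "gene",
) -> pd.DataFrame:
    """Unbiased scores: each labeled pair scored with its gene held out.

    For every gene with labeled pairs, the model is refit on all labeled
    pairs of the *other* genes and predicts the held-out gene's pairs —
    group leave-one-out, preventing leakage across tissues of the same
    gene.  Unlabeled pairs are scored once by the full model.
    """
    merged, pn, X, y = _labeled_xy(features, labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("leave-one-out needs both classes")
    full = _classifier(params, params.seed)
    full.fit(X, y)
    merged["score"] = predict_scores(full, merged)

    groups = pn[group_by].to_numpy()
    pn_scores = np.empty(len(pn))
    for g in np.unique(groups):
        held = groups == g
        y_tr = y[~held]
        if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
            raise DataError(f"holding out {g!r} leaves a single-class training set")
        clf = _classifier(params, params.seed)
        clf.fit(X[~held], y_tr)
        pn_scores[held] = clf.predict_proba(X[held])[:, 1]

    loo = pd.Series(pn_scores, index=pd.MultiIndex.from_frame(pn[["gene", "tissue"]]))
    key = pd.MultiIndex.from_frame(merged[["gene", "tissue"]])
    replace = key.isin(loo.index)
    merged.loc[replace, "score"] = loo.reindex(key[replace]).to_numpy()
    return make_score_table(merged)


def leave_one_tissue_out(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    params: ModelParams,
    tissue: str,
) -> pd.DataFrame:
    """Score one tissue's genes with a model never shown that tissue."""
    merged, pn, X, y = _labeled_xy(features, labels)
    train_mask = (pn["tissue"] != tissue).to_numpy()
    y_tr = y[train_mask]
    if len(y_tr) == 0 or y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
        raise DataError("no trainable rows remain outside the held-out tissue")
    clf = _classifier(params, params.seed)
    clf.fit(X[train_mask], y_tr)
    held = merged[merged["tissue"] == tissue].copy()
    if held.empty:
        raise DataError(f"unknown tissue: {tissue!r}")
    held["score"] = predict_scores(clf, held)
    return make_score_table(held)


def feature_importances(model: XGBClassifier) -> pd.Series:
    """Split-count (F score) importance for all 14 features, zeros included."""
    booster = model.get_booster()
    raw = booster.get_score(importance_type="weight")
    names = booster.feature_names or [f"f{i}" for i in range(len(FEATURE_COLUMNS))]
    by_pos = {name: raw.get(name, 0.0) for name in names}
    return pd.Series(
        {feat: float(by_pos.get(f"f{i}", 0.0)) for i, feat in enumerate(FEATURE_COLUMNS)},
        name="importance",
    )
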