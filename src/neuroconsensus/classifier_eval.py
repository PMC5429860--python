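"""Disease-gene classification harness over healthy-brain expression models.

Positive genes come from a disease evidence table (keeping only the
high-confidence categories, e.g. syndromic and replicated); negatives from a
brain-elevated tissue-specificity table after removing "group enriched"
genes and any overlap with the positives.  Each gene's feature vector is its
expression profile across the model's brain structures (donor-averaged
z-scores by default).  Evaluation follows a two-step design: stratified
80/20 train/test split, stratified 10-fold cross-validation on the training
portion, and held-out metrics, with ROC/AUC computed by threshold sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

POSITIVE_KEEP_DEFAULT = frozenset({"syndromic", "replicated"})
EVIDENCE_VOCAB = frozenset({"syndromic", "replicated", "minimal", "hypothesized"})
SPECIFICITY_VOCAB = frozenset({"elevated", "group_enriched", "not_elevated"})


# ---------------------------------------------------------------------------
# Gene set assembly
# ---------------------------------------------------------------------------


def assemble_positive_set(
    table: pd.DataFrame, keep: Iterable[str] = POSITIVE_KEEP_DEFAULT
) -> frozenset:
    """Genes whose ``evidence_category`` is in ``keep``.

    The evidence table needs columns gene_id and evidence_category; unknown
    categories raise, an empty result raises.
    """
    keep = frozenset(keep)
    _check_table(table, "evidence_category")
    bad = set(table["evidence_category"]) - EVIDENCE_VOCAB
    if bad:
        raise ValueError(f"unknown evidence categories: {sorted(bad)}")
    out = frozenset(table.loc[table["evidence_category"].isin(keep), "gene_id"])
    if not out:
        raise ValueError(f"no genes with evidence in {sorted(keep)}")
    return out


def assemble_negative_set(table: pd.DataFrame, positives: Iterable[str]) -> frozenset:
    """Brain-elevated genes minus group-enriched genes minus positives."""
    _check_table(table, "specificity_category")
    bad = set(table["specificity_category"]) - SPECIFICITY_VOCAB
    if bad:
        raise ValueError(f"unknown specificity categories: {sorted(bad)}")
    elevated = set(table.loc[table["specificity_category"] == "elevated", "gene_id"])
    grouped = set(table.loc[table["specificity_category"] == "group_enriched", "gene_id"])
    out = frozenset(elevated - grouped - set(positives))
    if not out:
        raise ValueError("negative set is empty after filtering")
    return out


def _check_table(table: pd.DataFrame, category_col: str) -> None:
    if not {"gene_id", category_col} <= set(table.columns):
        raise ValueError(f"table must have columns gene_id, {category_col}")
    if table["gene_id"].duplicated().any():
        dups = sorted(set(table["gene_id"][table["gene_id"].duplicated()]))
        raise ValueError(f"duplicate gene ids: {dups[:5]}")


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Gene feature vectors over model structures with binary labels.

    ``X`` rows are genes, columns structures; ``y`` is 1 for the positive
    (disease) class, 0 for the negative class.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share the same gene index")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains NaN; impute before constructing")

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())

    def subset(self, genes: Sequence) -> "LabeledDataset":
        return LabeledDataset(self.X.loc[list(genes)], self.y.loc[list(genes)])


def build_feature_vectors(
    positives: Iterable[str],
    negatives: Iterable[str],
    model_expr: pd.DataFrame,
    fill_value: float = 0.0,
) -> LabeledDataset:
    """Join labeled gene sets against the model's gene x structure profiles.

    Genes absent from the model are dropped (logged); a class losing all its
    genes raises.  Missing per-structure values (structures a gene was never
    measured in) are imputed with ``fill_value`` (0 on the z scale) and the
    imputation count is logged.
    """
    positives, negatives = frozenset(positives), frozenset(negatives)
    both = positives & negatives
    if both:
        raise ValueError(f"genes in both classes: {sorted(both)[:5]}")
    rows, labels = [], []
    dropped = []
    for gene_set, lab in ((positives, 1), (negatives, 0)):
        for g in sorted(gene_set):
            if g in model_expr.index:
                rows.append(g)
                labels.append(lab)
            else:
                dropped.append(g)
    if dropped:
        logger.warning("%d labeled gene(s) absent from the expression model: %s",
                       len(dropped), dropped[:5])
    y = pd.Series(labels, index=rows)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("a class lost all its genes when joining against the model")
    X = model_expr.loc[rows].copy()
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        logger.info("imputed %d missing feature cells with %s", n_missing, fill_value)
        X = X.fillna(fill_value)
    return LabeledDataset(X, y)


# ---------------------------------------------------------------------------
# Splitting and cross-validation
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    train_genes: list
    test_genes: list


def stratified_split(
    d: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> SplitSpec:
    """Per-class random split; class sizes round to the nearest integer.

    Each class is shuffled independently and cut at
    round(train_fraction * n_class), so the class ratio of each partition is
    within one instance of the global ratio.  Reproducible from ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in (1, 0):
        members = list(d.y.index[d.y == lab])
        if len(members) < 2:
            raise ValueError(f"class {lab} has fewer than 2 members")
        order = rng.permutation(len(members))
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        shuffled = [members[i] for i in order]
        train.extend(shuffled[:n_train])
        test.extend(shuffled[n_train:])
    return SplitSpec(train_genes=sorted(train), test_genes=sorted(test))


def default_learner(seed: int = 0) -> RandomForestClassifier:
    """The default learner: a random forest with a fixed seed."""
    return RandomForestClassifier(n_estimators=100, random_state=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class PerfReport:
    """Classification metrics; rates live in [0, 1] and satisfy the usual
    identities (accuracy from the confusion counts, FPR + TNR = 1, F1 the
    harmonic mean of precision and TPR)."""

    accuracy: float
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    precision: float
    f1: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    confusion: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k)
             for k in ("accuracy", "tpr", "fpr", "tnr", "fnr", "precision", "f1", "auc")}
        d["confusion"] = dict(self.confusion)
        return d


def _metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict:
    pos, neg = tp + fn, tn + fp
    precision = tp / (tp + fp) if tp + fp else 0.0
    tpr = tp / pos if pos else 0.0
    out = {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "tpr": tpr,
        "fpr": fp / neg if neg else 0.0,
        "tnr": tn / neg if neg else 0.0,
        "fnr": fn / pos if pos else 0.0,
        "precision": precision,
        "f1": (2 * precision * tpr / (precision + tpr)) if precision + tpr else 0.0,
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
    assert abs(out["fpr"] + out["tnr"] - 1.0) < 1e-12 or neg == 0
    assert abs(out["tpr"] + out["fnr"] - 1.0) < 1e-12 or pos == 0
    return out


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by sweeping all score thresholds (ties grouped) + trapezoid AUC.

    The trapezoid AUC equals the Mann-Whitney probability that a random
    positive outscores a random negative, counting ties as one half.
    Constant scores give the chance diagonal (AUC 0.5) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    if np.all(scores == scores[0]):
        logger.warning("constant scores; ROC is the chance diagonal, AUC = 0.5")
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    # group tied scores
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp_cum = np.concatenate([[0], np.cumsum(p)])
    idx = np.concatenate([boundaries, [len(s)]])
    tps = tp_cum[idx]
    fps = idx - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> PerfReport:
    """Full metric set from positive-class scores at a decision threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    m = _metrics_from_confusion(tp, tn, fp, fn)
    if len(set(labels)) == 2:
        fpr, tpr, auc = roc_auc(scores, labels)
    else:
        fpr, tpr, auc = np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    return PerfReport(
        accuracy=m["accuracy"], tpr=m["tpr"], fpr=m["fpr"], tnr=m["tnr"],
        fnr=m["fnr"], precision=m["precision"], f1=m["f1"], auc=auc,
        roc_fpr=fpr, roc_tpr=tpr, confusion=m["confusion"],
    )


def _fit_score(learner, X_tr, y_tr, X_te) -> np.ndarray:
    try:
        model = clone(learner)
    except TypeError:
        import copy

        model = copy.deepcopy(learner)
    model.fit(X_tr, y_tr)
    proba = model.predict_proba(X_te)
    classes = list(getattr(model, "classes_", [0, 1]))
    return np.asarray(proba)[:, classes.index(1)]


def cross_validate(
    d: LabeledDataset, learner=None, k: int = 10, seed: int = 0
) -> PerfReport:
    """Stratified k-fold cross-validation; aggregate = pooled predictions.

    Every gene appears in exactly one test fold; each fold keeps the class
    ratio within one instance of the global ratio.  Per-fold metric dicts
    are attached to the returned report.
    """
    if d.n_pos < k or d.n_neg < k:
        raise ValueError(f"each class needs >= k={k} members for stratified {k}-fold CV")
    learner = learner if learner is not None else default_learner(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = d.X.to_numpy(dtype=float)
    y = d.y.to_numpy(dtype=int)
    pooled_scores = np.empty(len(y))
    per_fold = []
    for tr, te in skf.split(X, y):
        if len(set(y[tr])) < 2 or len(set(y[te])) < 2:
            raise ValueError("degenerate single-class fold")
        scores = _fit_score(learner, X[tr], y[tr], X[te])
        pooled_scores[te] = scores
        per_fold.append(evaluate_predictions(y[te], scores).to_dict())
    report = evaluate_predictions(y, pooled_scores)
    report.per_fold = per_fold
    return report


def train_test_evaluate(
    d: LabeledDataset, split: SplitSpec, learner=None, seed: int = 0
) -> PerfReport:
    """Fit on the training genes, report metrics on the held-out test genes."""
    learner = learner if learner is not None else default_learner(seed)
    tr, te = d.subset(split.train_genes), d.subset(split.test_genes)
    scores = _fit_score(learner, tr.X.to_numpy(float), tr.y.to_numpy(int),
                        te.X.to_numpy(float))
    return evaluate_predictions(te.y.to_numpy(int), scores)


def rank_candidates(
    d: LabeledDataset, candidates_expr: pd.DataFrame, learner=None, seed: int = 0,
    fill_value: float = 0.0,
) -> pd.Series:
    """Score unlabeled genes by positive-class probability, ranked descending.

    This is the model's end use: proposing novel disease-gene candidates
    from the full gene complement.
    """
    learner = learner if learner is not None else default_learner(seed)
    X_new = candidates_expr.reindex(columns=d.X.columns).fillna(fill_value)
    scores = _fit_score(learner, d.X.to_numpy(float), d.y.to_numpy(int),
                        X_new.to_numpy(float))
    return pd.Series(scores, index=candidates_expr.index).sort_values(
        ascending=False, kind="stable"
    )
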