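"""Classifier bench: 22-feature matrix, five models under stratified 10-fold
cross-validation, confusion-matrix metrics, pooled ROC/AUC, DeLong AUC
comparison, and SHAP-style interpretation.

Feature column order is fixed: the 9 graph features followed by the 13 RQA
features. TPE is the positive class. Out-of-fold probability scores are
pooled across folds (all models score the same subjects, which the paired
DeLong comparison requires); hard labels are taken at probability 0.5, and
the confusion-count metric formulas are applied literally.

SHAP values for the boosted-tree model come from XGBoost's native TreeSHAP
(``pred_contribs`` / ``pred_interactions``: exact path-dependent Shapley
values). For other models a Monte-Carlo permutation-sampling Shapley
approximation is provided and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .graphs import GRAPH_FEATURE_NAMES, GraphFeatureSet
from .rqa import RQA_FEATURE_NAMES

__all__ = [
    "FEATURE_COLUMNS",
    "MODEL_NAMES",
    "FeatureMatrix",
    "ClassifierReport",
    "assemble_feature_matrix",
    "crossval_evaluate",
    "delong_compare",
    "shap_analysis",
]

FEATURE_COLUMNS: list[str] = GRAPH_FEATURE_NAMES + RQA_FEATURE_NAMES  # 9 + 13
MODEL_NAMES = ["xgboost", "logistic", "svm", "random_forest", "naive_bayes"]
POSITIVE_GROUP = "TPE"


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # subjects x 22, columns FEATURE_COLUMNS
    y: pd.Series  # 1 = TPE (positive), 0 = TLE

    def __post_init__(self) -> None:
        if list(self.X.columns) != FEATURE_COLUMNS:
            raise ValueError("feature columns must follow the fixed 22-column order")
        if self.X.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        if not self.X.index.equals(self.y.index):
            raise ValueError("labels must align with feature rows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


@dataclass
class ClassifierReport:
    model: str
    tp: int
    fn: int
    tn: int
    fp: int
    scores: np.ndarray  # pooled out-of-fold P(TPE)
    y: np.ndarray
    auc: float
    roc: tuple[np.ndarray, np.ndarray]  # fpr, tpr
    seed: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
        }


def assemble_feature_matrix(
    graph_sets: dict[str, GraphFeatureSet],
    rqa_sets: dict[str, pd.Series],
    groups: pd.Series,
) -> FeatureMatrix:
    """Join per-subject graph and RQA features in the fixed column order."""
    subject_ids = sorted(groups.index)
    rows = []
    for sid in subject_ids:
        if sid not in graph_sets:
            raise ValueError(f"missing graph features for subject {sid}")
        if sid not in rqa_sets:
            raise ValueError(f"missing RQA features for subject {sid}")
        rows.append(
            np.concatenate([
                graph_sets[sid].to_array(),
                rqa_sets[sid].reindex(RQA_FEATURE_NAMES).to_numpy(),
            ])
        )
    X = pd.DataFrame(rows, index=subject_ids, columns=FEATURE_COLUMNS)
    y = (groups.loc[subject_ids] == POSITIVE_GROUP).astype(int)
    return FeatureMatrix(X=X, y=y)


def make_model(name: str, seed: int = 0):
    """Library-default classifiers behind a per-fold standardization step."""
    if name == "xgboost":
        # exact greedy splits: at n ~ 50 the histogram approximation puts
        # thresholds on data points instead of gap midpoints
        clf = XGBClassifier(random_state=seed, eval_metric="logloss",
                            verbosity=0, tree_method="exact")
    elif name == "logistic":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
    elif name == "svm":
        clf = SVC(probability=True, random_state=seed)
    elif name == "random_forest":
        clf = RandomForestClassifier(random_state=seed)
    elif name == "naive_bayes":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return make_pipeline(StandardScaler(), clf)


def crossval_evaluate(
    fm: FeatureMatrix, model: str, k: int = 10, seed: int = 0
) -> ClassifierReport:
    """Stratified k-fold CV with pooled out-of-fold scores."""
    y = fm.y.to_numpy()
    counts = np.bincount(y)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")
    X = fm.X.to_numpy(float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for train, test in skf.split(X, y):
        pipe = make_model(model, seed=seed)
        pipe.fit(X[train], y[train])
        scores[test] = pipe.predict_proba(X[test])[:, 1]
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return ClassifierReport(
        model=model, tp=tp, fn=fn, tn=tn, fp=fp, scores=scores, y=y,
        auc=auc, roc=(fpr, tpr), seed=seed,
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) and the AUC."""
    m, n = pos.size, neg.size
    v10 = np.empty(m)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    return v10, v01, float(v10.mean())


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns (auc_a, auc_b, z, two-sided p). Scores must be aligned to the
    same subjects; y = 1 marks the positive class.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    pos, neg = y == 1, y == 0
    va10, va01, auc_a = _placements(scores_a[pos], scores_a[neg])
    vb10, vb01, auc_b = _placements(scores_b[pos], scores_b[neg])
    m, n = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.stack([va10, vb10]))  # 2x2 over positives
    s01 = np.cov(np.stack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
    p = 1.0 if not np.isfinite(z) and delta == 0 else float(2 * sps.norm.sf(abs(z)))
    if var <= 0 and delta == 0:
        z, p = 0.0, 1.0
    return auc_a, auc_b, float(z), p


@dataclass
class ShapSummary:
    importance: pd.Series  # mean |SHAP| per feature, descending
    values: np.ndarray  # subjects x features SHAP values
    base_value: float
    interactions: pd.DataFrame | None = None  # mean |interaction| per pair
    approximate: bool = False


def shap_analysis(
    fm: FeatureMatrix, model: str = "xgboost", seed: int = 0,
    n_samples: int = 200,
) -> ShapSummary:
    """SHAP importance (and, for the tree model, interactions) on a full fit.

    The model is fitted on the whole feature matrix (interpretation, not
    performance estimation). XGBoost provides exact TreeSHAP contributions
    and pairwise interaction values; other models fall back to a seeded
    Monte-Carlo permutation-sampling approximation (flagged).
    """
    import xgboost as xgb

    X = fm.X.to_numpy(float)
    y = fm.y.to_numpy()
    if model == "xgboost":
        clf = XGBClassifier(random_state=seed, eval_metric="logloss",
                            verbosity=0, tree_method="exact")
        clf.fit(X, y)
        dm = xgb.DMatrix(X, feature_names=FEATURE_COLUMNS)
        contribs = clf.get_booster().predict(dm, pred_contribs=True)
        values, base = contribs[:, :-1], float(contribs[0, -1])
        inter = clf.get_booster().predict(dm, pred_interactions=True)
        inter_mean = np.abs(inter[:, :-1, :-1]).mean(axis=0)
        interactions = pd.DataFrame(
            inter_mean, index=FEATURE_COLUMNS, columns=FEATURE_COLUMNS
        )
        approx = False
    else:
        pipe = make_model(model, seed=seed)
        pipe.fit(X, y)
        values, base = _sampling_shap(
            lambda Z: pipe.predict_proba(Z)[:, 1], X, n_samples=n_samples, seed=seed
        )
        interactions = None
        approx = True
    imp = pd.Series(
        np.abs(values).mean(axis=0), index=FEATURE_COLUMNS
    ).sort_values(ascending=False)
    return ShapSummary(
        importance=imp, values=values, base_value=base,
        interactions=interactions, approximate=approx,
    )


def _sampling_shap(
    predict, X: np.ndarray, n_samples: int, seed: int
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values against the dataset mean background."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    background = X.mean(axis=0)
    base = float(predict(background[None, :])[0])
    values = np.zeros((n, p))
    for _ in range(n_samples):
        perm = rng.permutation(p)
        # build the chain of coalitions for every subject at once
        Z = np.tile(background, (n, 1))
        prev = predict(Z)
        for j in perm:
            Z[:, j] = X[:, j]
            cur = predict(Z)
            values[:, j] += cur - prev
            prev = cur
    return values / n_samples, base
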