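"""Primer-efficiency decision support.

Four classifier families — logistic regression, RBF support-vector machine,
decision tree and random forest — are trained on the 18 numeric template
parameters to predict whether a designed primer will genotype efficiently
(high depth, low missing rate). Model selection uses ROC/AUC over repeated
stratified holdout splits; AUC is the Mann-Whitney probability that a random
efficient primer outscores a random non-efficient one (ties count 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .templates import FEATURE_NAMES

MODEL_FAMILIES = ("logistic_regression", "svm", "decision_tree", "random_forest")

#: AUC interpretation bands: value below the key bound falls in that band
AUC_BANDS = [
    (0.60, "poor"),
    (0.75, "moderate"),
    (0.90, "good"),
    (1.0 + 1e-12, "very good"),
]


def auc_band(value: float) -> str:
    """Qualitative interpretation of an AUC value (poor < 0.60 <= moderate
    < 0.75 <= good < 0.90 <= very good)."""
    for bound, label in AUC_BANDS:
        if value < bound:
            return label
    return "very good"


def auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability that a random positive outscores
    a random negative, with ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class LabeledTemplate:
    """An 18-parameter feature vector with its efficiency label."""

    features: np.ndarray
    label: int  # 1 = efficient, 0 = non-efficient

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {self.features.shape}")


@dataclass
class ModelReport:
    auc: dict[str, float]
    auc_interpretation: dict[str, str]
    accuracy: dict[str, float]
    roc_points: dict[str, np.ndarray]  # (fpr, tpr) pairs, monotone in fpr
    best_model: str
    feature_importances: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    fitted: dict[str, object] = field(default_factory=dict)


def _make_models(seed: int) -> dict[str, object]:
    # hyperparameters fixed by design: 500-tree forest, unlimited depth,
    # RBF-kernel SVM with default scale, L2 logistic regression
    return {
        "logistic_regression": LogisticRegression(max_iter=5000),  # L2 by default
        # RBF-kernel SVM; Platt-calibrated so all four families score on a
        # common probability scale
        "svm": CalibratedClassifierCV(
            SVC(kernel="rbf", gamma="scale", random_state=seed), ensemble=False
        ),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "random_forest": RandomForestClassifier(
            n_estimators=500, max_depth=None, random_state=seed
        ),
    }


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tp = np.concatenate([[0], np.cumsum(y == 1)])
    fp = np.concatenate([[0], np.cumsum(y == 0)])
    tpr = tp / max(1, (labels == 1).sum())
    fpr = fp / max(1, (labels == 0).sum())
    return np.column_stack([fpr, tpr])


def cross_validate(
    data: list[LabeledTemplate],
    models: tuple[str, ...] = MODEL_FAMILIES,
    test_size: float = 0.3,
    repeats: int = 50,
    seed: int = 0,
) -> ModelReport:
    """Repeated stratified holdout evaluation of the four model families.

    Each repeat splits the labeled templates ``(1 - test_size)/test_size``
    stratified by class, fits every requested model on the training part and
    scores the held-out part. AUC and accuracy (0.5 probability threshold)
    are averaged over repeats; ROC points pool the held-out scores of all
    repeats. The report names the best model by mean AUC.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 labeled templates")
    X = np.vstack([d.features for d in data])
    y = np.array([d.label for d in data], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both efficient and non-efficient classes must be present")

    unknown = set(models) - set(MODEL_FAMILIES)
    if unknown:
        raise ValueError(f"unknown model families: {sorted(unknown)}")

    splitter = StratifiedShuffleSplit(n_splits=repeats, test_size=test_size, random_state=seed)
    aucs: dict[str, list[float]] = {m: [] for m in models}
    accs: dict[str, list[float]] = {m: [] for m in models}
    pooled_scores: dict[str, list[np.ndarray]] = {m: [] for m in models}
    pooled_labels: list[np.ndarray] = []
    fitted: dict[str, object] = {}

    for rep, (train, test) in enumerate(splitter.split(X, y)):
        model_objs = _make_models(seed + rep)
        pooled_labels.append(y[test])
        for name in models:
            model = model_objs[name]
            model.fit(X[train], y[train])
            prob = model.predict_proba(X[test])[:, 1]
            aucs[name].append(auc(prob, y[test]))
            accs[name].append(float(((prob >= 0.5).astype(int) == y[test]).mean()))
            pooled_scores[name].append(prob)
            fitted[name] = model

    all_labels = np.concatenate(pooled_labels)
    mean_auc = {m: float(np.mean(aucs[m])) for m in models}
    best = max(models, key=lambda m: mean_auc[m])
    report = ModelReport(
        auc=mean_auc,
        auc_interpretation={m: auc_band(mean_auc[m]) for m in models},
        accuracy={m: float(np.mean(accs[m])) for m in models},
        roc_points={
            m: _roc_points(np.concatenate(pooled_scores[m]), all_labels) for m in models
        },
        best_model=best,
        fitted=fitted,
    )
    for name in ("decision_tree", "random_forest"):
        if name in fitted:
            report.feature_importances[name] = list(
                zip(FEATURE_NAMES, fitted[name].feature_importances_)
            )
    return report


def rank_features(forest) -> list[str]:
    """The 18 parameter names ordered by decreasing mean impurity-decrease
    importance of a fitted random forest."""
    try:
        importances = forest.feature_importances_
    except Exception as exc:  # includes sklearn NotFittedError
        raise ValueError("model is not a fitted forest") from exc
    order = np.argsort(-np.asarray(importances), kind="mergesort")
    return [FEATURE_NAMES[i] for i in order]


def label_templates(
    feature_matrix: np.ndarray,
    mean_depths: np.ndarray,
    missing_rates: np.ndarray,
    min_depth: float = 50.0,
    max_missing: float = 0.10,
) -> list[LabeledTemplate]:
    """Label templates efficient/non-efficient from observed genotyping
    performance: efficient = mean depth >= ``min_depth`` and missing rate
    <= ``max_missing`` (the >50x / <10% working thresholds)."""
    out = []
    for feats, d, miss in zip(feature_matrix, mean_depths, missing_rates):
        out.append(LabeledTemplate(feats, int(d >= min_depth and miss <= max_missing)))
    return out
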