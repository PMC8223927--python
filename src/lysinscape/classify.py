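"""Random-forest prediction of the host Gram group from sequence features.

Two feature sets are supported: ``physchem4`` (NCPR, average hydrophobic
moment, aliphatic index, GRAVY) and ``extended7`` (those plus protein
length, number of PF hits and the signal-peptide flag).  The protocol is a
stratified 75/25 split, a forest with a fixed number of candidate variables
per node (mtry 4) sanity-checked by 5-fold × 3-repeat cross-validation on
the training set, ROC analysis of the held-out G+ probabilities, best-point
thresholding by the Youden criterion (maximize TPR − FPR), and mean
impurity-decrease (Gini) importances.  G+ is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    cross_val_score,
    train_test_split,
)

__all__ = [
    "PHYSCHEM4",
    "EXTENDED7",
    "ClassifierConfig",
    "ClassifierReport",
    "split_train_test",
    "fit_evaluate",
    "rank_importance",
]

PHYSCHEM4 = ("ncpr", "avg_hydrophobic_moment", "aliphatic_index", "gravy")
EXTENDED7 = PHYSCHEM4 + ("length", "n_pf_hits", "signal_peptide")

_FEATURE_SETS = {"physchem4": PHYSCHEM4, "extended7": EXTENDED7}

POSITIVE = "G+"


@dataclass
class ClassifierConfig:
    features: str | tuple[str, ...] = "physchem4"
    train_fraction: float = 0.75
    cv_folds: int = 5
    cv_repeats: int = 3
    mtry: int = 4
    n_trees: int = 500
    seed: int = 0
    #: whole-sequence net charge is redundant with NCPR × length and is off
    #: by default; flip on to add it to the feature set
    include_net_charge: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train fraction must lie in (0, 1)")

    def feature_names(self) -> list[str]:
        names = list(
            _FEATURE_SETS[self.features]
            if isinstance(self.features, str)
            else self.features
        )
        if self.include_net_charge and "net_charge" not in names:
            names.append("net_charge")
        return names


@dataclass
class ClassifierReport:
    features: list[str]
    roc: pd.DataFrame  # fpr, tpr, threshold
    auc: float
    best_threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame  # rows true, cols predicted
    importances: pd.Series  # mean Gini decrease per feature
    cv_scores: np.ndarray
    model: RandomForestClassifier = field(repr=False, default=None)


def _labelled(features: pd.DataFrame) -> pd.DataFrame:
    df = features.dropna(subset=["gram"])
    classes = set(df["gram"].unique())
    if classes != {"G+", "G-"}:
        raise ValueError(f"need both Gram classes, got {sorted(classes)}")
    return df


def split_train_test(
    features: pd.DataFrame, config: ClassifierConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label random split at the configured training fraction."""
    cfg = config or ClassifierConfig()
    df = _labelled(features)
    train, test = train_test_split(
        df,
        train_size=cfg.train_fraction,
        stratify=df["gram"],
        random_state=cfg.seed,
    )
    return train, test


def fit_evaluate(
    features: pd.DataFrame, config: ClassifierConfig | None = None
) -> ClassifierReport:
    """Fit on the training split, evaluate ROC/threshold metrics on the test split."""
    cfg = config or ClassifierConfig()
    names = cfg.feature_names()
    train, test = split_train_test(features, cfg)
    if test["gram"].nunique() < 2:
        raise ValueError("test split is single-class; cannot compute a ROC curve")
    X_tr = train[names].astype(float).to_numpy()
    y_tr = (train["gram"] == POSITIVE).to_numpy()
    X_te = test[names].astype(float).to_numpy()
    y_te = (test["gram"] == POSITIVE).to_numpy()

    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=min(cfg.mtry, len(names)),
        random_state=cfg.seed,
        n_jobs=1,
    )
    cv = RepeatedStratifiedKFold(
        n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats, random_state=cfg.seed
    )
    cv_scores = cross_val_score(forest, X_tr, y_tr, cv=cv, scoring="accuracy")
    forest.fit(X_tr, y_tr)

    prob = forest.predict_proba(X_te)[:, list(forest.classes_).index(True)]
    fpr, tpr, thresholds = roc_curve(y_te, prob)
    roc_auc = float(auc(fpr, tpr))
    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # tie-break: the lower threshold (favors sensitivity); roc_curve returns
    # thresholds in decreasing order so that is the last tied index
    b = int(best[-1])
    threshold = float(min(thresholds[b], 1.0))

    pred = prob >= threshold
    tp = int(np.sum(pred & y_te))
    tn = int(np.sum(~pred & ~y_te))
    fp = int(np.sum(pred & ~y_te))
    fn = int(np.sum(~pred & y_te))
    confusion = pd.DataFrame(
        [[tn, fp], [fn, tp]],
        index=pd.Index(["G-", "G+"], name="true"),
        columns=pd.Index(["G-", "G+"], name="predicted"),
    )
    return ClassifierReport(
        features=names,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        auc=roc_auc,
        best_threshold=threshold,
        accuracy=(tp + tn) / len(y_te),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        confusion=confusion,
        importances=pd.Series(forest.feature_importances_, index=names),
        cv_scores=cv_scores,
        model=forest,
    )


def rank_importance(report: ClassifierReport) -> list[str]:
    """Features by decreasing mean Gini decrease; ties broken alphabetically."""
    s = report.importances
    return sorted(s.index, key=lambda f: (-s[f], f))
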