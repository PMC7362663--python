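"""Two-level hierarchical tissue classification.

Level 1 separates infarct core (IC) from non-IC using the 18 relative-DTI
features only.  Level 2 then separates penumbra (IP) from normal tissue
(NT) among the non-IC voxels using all 110 features, where the two
Mahalanobis features are computed against the IC feature distribution
frozen from the level-1 training voxels.  A single-level 3-class model on
the 18 DTI features serves as the comparison arm.

Backends: RBF-kernel SVM (C = 1, kernel scale from the median pairwise
distance heuristic), k-nearest neighbours (k = 5), and a CART decision
tree.  Features are standardised to train-set mean/SD before SVM and KNN
fitting.  All backends run through the same interface and are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (
    IcDistribution,
    dti_block_names,
    feature_names,
    fit_ic_distribution,
    mahalanobis_block,
)
from .labeling import LABEL_IC, LABEL_IP, LABEL_NT

__all__ = [
    "BACKENDS",
    "FittedClassifier",
    "TwoLevelModel",
    "SingleLevelModel",
    "Prediction",
    "train_two_level",
    "predict_two_level",
    "train_single_level",
    "predict_single_level",
]

BACKENDS = ("svm", "knn", "tree")


def _median_gamma(x: np.ndarray, seed: int, max_rows: int = 500) -> float:
    """RBF gamma = 1/(2 m^2) with m the median pairwise distance (subsampled)."""
    rng = np.random.default_rng(seed)
    if x.shape[0] > max_rows:
        x = x[rng.choice(x.shape[0], max_rows, replace=False)]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    d = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
    d = d[d > 0]
    if d.size == 0:
        return 1.0 / x.shape[1]
    med = float(np.median(d))
    return 1.0 / (2.0 * med**2)


@dataclass
class FittedClassifier:
    """A standardiser plus fitted estimator with a uniform score interface."""

    scaler: StandardScaler
    clf: object
    backend: str

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.clf.predict(self.scaler.transform(x))

    def score_positive(self, x: np.ndarray) -> np.ndarray:
        """Continuous score for the positive (label 1) class of a binary fit."""
        xs = self.scaler.transform(x)
        if hasattr(self.clf, "decision_function"):
            return np.asarray(self.clf.decision_function(xs), dtype=float)
        proba = self.clf.predict_proba(xs)
        pos_idx = int(np.where(self.clf.classes_ == 1)[0][0])
        return proba[:, pos_idx]


def _fit_backend(x: np.ndarray, y: np.ndarray, backend: str, seed: int, class_weight=None) -> FittedClassifier:
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    if backend == "svm":
        clf = SVC(C=1.0, kernel="rbf", gamma=_median_gamma(xs, seed), class_weight=class_weight)
    elif backend == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        clf = DecisionTreeClassifier(random_state=seed, class_weight=class_weight)
    clf.fit(xs, y)
    return FittedClassifier(scaler=scaler, clf=clf, backend=backend)


@dataclass
class TwoLevelModel:
    level1: FittedClassifier
    level2: FittedClassifier
    ic_distribution: IcDistribution
    backend: str
    training_meta: dict = field(default_factory=dict)


@dataclass
class SingleLevelModel:
    clf: FittedClassifier
    backend: str
    training_meta: dict = field(default_factory=dict)


@dataclass
class Prediction:
    """Per-voxel predicted classes plus decision scores from both levels.

    ``score_level1`` is the IC-vs-nonIC score for every voxel; voxels that
    level 1 already called IC never receive a level-2 score (NaN).
    """

    label: np.ndarray
    score_level1: np.ndarray
    score_level2: np.ndarray


def _check_classes(df: pd.DataFrame) -> None:
    present = set(df["label"].unique())
    missing = {LABEL_IC, LABEL_IP, LABEL_NT} - present
    if missing:
        raise ValueError(f"training data lacks label classes {sorted(missing)}")


def train_two_level(
    train: pd.DataFrame, backend: str = "svm", seed: int = 0, balanced: bool = False
) -> TwoLevelModel:
    """Fit level 1 (IC vs non-IC, 18 features) then level 2 (IP vs NT, 110).

    The IC feature distribution is fitted on the *labelled* IC training
    voxels and the Mahalanobis block of the non-IC training rows is
    recomputed against it before level-2 fitting, so both levels see
    exactly what they will see at prediction time.
    """
    _check_classes(train)
    cw = "balanced" if balanced else None
    dti_cols = dti_block_names()
    all_cols = feature_names()

    x1 = train[dti_cols].to_numpy(dtype=float)
    y1 = (train["label"].to_numpy() == LABEL_IC).astype(int)
    level1 = _fit_backend(x1, y1, backend, seed, cw)

    dist = fit_ic_distribution(x1[y1 == 1])

    non_ic = train["label"].to_numpy() != LABEL_IC
    x2 = train.loc[non_ic, all_cols].to_numpy(dtype=float)
    x2[:, -2:] = mahalanobis_block(x1[non_ic], dist)
    y2 = (train.loc[non_ic, "label"].to_numpy() == LABEL_IP).astype(int)
    level2 = _fit_backend(x2, y2, backend, seed, cw)

    meta = {
        "rat_ids": sorted(map(str, train["rat_id"].unique())),
        "backend": backend,
        "seed": seed,
        "n_train_rows": int(len(train)),
        "balanced": balanced,
    }
    return TwoLevelModel(level1=level1, level2=level2, ic_distribution=dist, backend=backend, training_meta=meta)


def predict_two_level(model: TwoLevelModel, test: pd.DataFrame) -> Prediction:
    """Hierarchical prediction: IC first, then IP vs NT for the remainder."""
    dti_cols = dti_block_names()
    all_cols = feature_names()
    missing = [c for c in all_cols if c not in test.columns]
    if missing:
        raise ValueError(f"test feature matrix lacks columns {missing[:5]}...")

    x1 = test[dti_cols].to_numpy(dtype=float)
    is_ic = model.level1.predict(x1) == 1
    score1 = model.level1.score_positive(x1)

    label = np.full(len(test), LABEL_NT, dtype=int)
    label[is_ic] = LABEL_IC
    score2 = np.full(len(test), np.nan)
    if (~is_ic).any():
        x2 = test.loc[~is_ic, all_cols].to_numpy(dtype=float)
        x2[:, -2:] = mahalanobis_block(x1[~is_ic], model.ic_distribution)
        is_ip = model.level2.predict(x2) == 1
        sub = np.where(~is_ic)[0]
        label[sub[is_ip]] = LABEL_IP
        score2[sub] = model.level2.score_positive(x2)
    return Prediction(label=label, score_level1=score1, score_level2=score2)


def train_single_level(
    train: pd.DataFrame, backend: str = "svm", seed: int = 0, balanced: bool = False
) -> SingleLevelModel:
    """3-class baseline on the 18 relative-DTI features only."""
    _check_classes(train)
    cw = "balanced" if balanced else None
    x = train[dti_block_names()].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    clf = _fit_backend(x, y, backend, seed, cw)
    meta = {
        "rat_ids": sorted(map(str, train["rat_id"].unique())),
        "backend": backend,
        "seed": seed,
    }
    return SingleLevelModel(clf=clf, backend=backend, training_meta=meta)


def predict_single_level(model: SingleLevelModel, test: pd.DataFrame) -> np.ndarray:
    """Predicted class codes from the 18-dim block alone."""
    return model.clf.predict(test[dti_block_names()].to_numpy(dtype=float)).astype(int)
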