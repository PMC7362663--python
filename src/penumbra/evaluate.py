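"""Cross-validated evaluation of the tissue classifiers.

The validation design is subject-level leave-one-out cross-validation
(LOOCV): each fold trains on all animals but one and tests on the held-out
animal, so no voxel of the test animal — including the infarct-core
feature distribution behind the Mahalanobis features — ever influences the
fitted model.  A stratified voxel-level k-fold split of the pooled
training data provides the within-training estimate.

Reported quantities: accuracy (percent), sensitivity and specificity
(fractions) and AUC for the two binary stages (IC vs non-IC over all
hemisphere voxels; IP vs NT among voxels both reference and prediction
call non-IC), 3-class hemisphere accuracy, per-slice tissue volumes with a
Pearson correlation between estimated and reference volumes, and a
two-sided Mann-Whitney U-test comparing per-animal total volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import (
    Prediction,
    predict_single_level,
    predict_two_level,
    train_single_level,
    train_two_level,
)
from .labeling import LABEL_IC, LABEL_IP, LABEL_NT

__all__ = [
    "EvalReport",
    "loocv_split",
    "kfold_split",
    "confusion_metrics",
    "roc_auc",
    "slice_volume_correspondence",
    "volume_comparison_test",
    "run_loocv",
    "kfold_cv_report",
]

TISSUES = {"IC": LABEL_IC, "IP": LABEL_IP, "NT": LABEL_NT}


def loocv_split(rat_ids: list[str]) -> list[tuple[list[str], str]]:
    """One fold per animal: (training ids, held-out id)."""
    ids = list(rat_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate rat IDs in LOOCV split")
    if len(ids) < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    return [([r for r in ids if r != test], test) for test in ids]


def kfold_split(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold row split; unstratified fallback if a class < k."""
    labels = np.asarray(labels)
    if labels.size < k:
        raise ValueError(f"need at least {k} rows for {k}-fold CV")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(f"smallest class has {counts.min()} < {k} members; falling back to unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(labels))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(labels, labels))


def confusion_metrics(pred: np.ndarray, truth: np.ndarray, positive_class) -> dict[str, float]:
    """Binary accuracy (percent), sensitivity and specificity (fractions)."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("prediction and truth must be non-empty aligned vectors")
    p = pred == positive_class
    t = truth == positive_class
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fn = int((~p & t).sum())
    fp = int((p & ~t).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = 100.0 * (tp + tn) / pred.size
    return {"accuracy_pct": acc, "sensitivity": sens, "specificity": spec}


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC (ties count one half); NaN if only one class present."""
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    ok = np.isfinite(scores)
    truth, scores = truth[ok], scores[ok]
    if truth.size == 0 or len(np.unique(truth)) < 2:
        return float("nan")
    return float(roc_auc_score(truth, scores))


def slice_volume_correspondence(
    pred_vols: pd.DataFrame,
) -> dict[str, float]:
    """Pearson r per tissue between per-slice estimated and reference volumes.

    Expects a long table with columns (rat_id, slice, tissue, vol_pred_mm3,
    vol_ref_mm3); returns NaN for a tissue whose series has zero variance.
    """
    out: dict[str, float] = {}
    for tissue, sub in pred_vols.groupby("tissue"):
        x = sub["vol_ref_mm3"].to_numpy(dtype=float)
        y = sub["vol_pred_mm3"].to_numpy(dtype=float)
        if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
            out[str(tissue)] = float("nan")
        else:
            out[str(tissue)] = float(pearsonr(x, y)[0])
    return out


def per_slice_volumes(
    df: pd.DataFrame, pred_label: np.ndarray, voxel_volume_mm3: float
) -> pd.DataFrame:
    """Per (rat, slice, tissue) volumes under the predicted and reference labels."""
    rows = []
    ref = df["label"].to_numpy(dtype=int)
    for (rat, sl), idx in df.groupby(["rat_id", "slice"]).indices.items():
        for tissue, code in TISSUES.items():
            rows.append(
                {
                    "rat_id": rat,
                    "slice": int(sl),
                    "tissue": tissue,
                    "vol_pred_mm3": float((pred_label[idx] == code).sum() * voxel_volume_mm3),
                    "vol_ref_mm3": float((ref[idx] == code).sum() * voxel_volume_mm3),
                }
            )
    return pd.DataFrame(rows)


def volume_comparison_test(pred_vols: np.ndarray, ref_vols: np.ndarray) -> float:
    """Two-sided Mann-Whitney U-test on per-animal volumes.

    Exact null distribution for small samples without ties; normal
    approximation with tie correction otherwise; fully tied data give p=1.
    """
    x = np.asarray(pred_vols, dtype=float)
    y = np.asarray(ref_vols, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


@dataclass
class EvalReport:
    """Per-fold and pooled LOOCV results plus volume analyses."""

    folds: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    pearson_r: dict = field(default_factory=dict)
    volume_p: dict = field(default_factory=dict)
    slice_volumes: pd.DataFrame | None = None
    single_level: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "folds": self.folds,
            "pooled": self.pooled,
            "pearson_r": self.pearson_r,
            "volume_p": self.volume_p,
            "single_level": self.single_level,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _fold_metrics(test: pd.DataFrame, pred: Prediction) -> dict:
    truth = test["label"].to_numpy(dtype=int)
    ic = confusion_metrics(pred.label, truth, LABEL_IC)
    ic["auc"] = roc_auc(pred.score_level1, (truth == LABEL_IC).astype(int))

    non_ic = (truth != LABEL_IC) & (pred.label != LABEL_IC)
    if non_ic.sum() > 0 and len(np.unique(truth[non_ic])) > 0:
        ipnt = confusion_metrics(pred.label[non_ic], truth[non_ic], LABEL_IP)
        ipnt["auc"] = roc_auc(pred.score_level2[non_ic], (truth[non_ic] == LABEL_IP).astype(int))
    else:
        ipnt = {"accuracy_pct": np.nan, "sensitivity": np.nan, "specificity": np.nan, "auc": np.nan}

    return {
        "n_voxels": int(len(test)),
        "ic_vs_nonic": ic,
        "ip_vs_nt": ipnt,
        "hemisphere_accuracy_pct": 100.0 * float(np.mean(pred.label == truth)),
    }


def run_loocv(
    features_by_rat: dict[str, pd.DataFrame],
    backend: str = "svm",
    seed: int = 0,
    voxel_volume_mm3: float = 0.16 * 0.16 * 1.0,
    include_single_level: bool = True,
    balanced: bool = False,
) -> EvalReport:
    """Full LOOCV over animals with the two-level model (and baseline)."""
    report = EvalReport(meta={"backend": backend, "seed": seed, "n_rats": len(features_by_rat)})
    all_pred: list[np.ndarray] = []
    all_truth: list[np.ndarray] = []
    all_s1: list[np.ndarray] = []
    all_s2: list[np.ndarray] = []
    all_single: list[np.ndarray] = []
    vol_tables: list[pd.DataFrame] = []

    for train_ids, test_id in loocv_split(sorted(features_by_rat)):
        train = pd.concat([features_by_rat[r] for r in train_ids], ignore_index=True)
        test = features_by_rat[test_id].reset_index(drop=True)
        model = train_two_level(train, backend=backend, seed=seed, balanced=balanced)
        assert test_id not in model.training_meta["rat_ids"], "LOOCV leakage: test rat in training meta"
        pred = predict_two_level(model, test)

        fold = _fold_metrics(test, pred)
        fold["test_rat"] = test_id
        fold["train_rats"] = list(train_ids)
        report.folds.append(fold)

        all_pred.append(pred.label)
        all_truth.append(test["label"].to_numpy(dtype=int))
        all_s1.append(pred.score_level1)
        all_s2.append(pred.score_level2)
        vol_tables.append(per_slice_volumes(test, pred.label, voxel_volume_mm3))

        if include_single_level:
            smodel = train_single_level(train, backend=backend, seed=seed, balanced=balanced)
            all_single.append(predict_single_level(smodel, test))

    pred_cat = np.concatenate(all_pred)
    truth_cat = np.concatenate(all_truth)
    pooled = _pooled_metrics(pred_cat, truth_cat, np.concatenate(all_s1), np.concatenate(all_s2))
    report.pooled = pooled

    slice_vols = pd.concat(vol_tables, ignore_index=True)
    report.slice_volumes = slice_vols
    report.pearson_r = slice_volume_correspondence(slice_vols)

    rat_vols = slice_vols.groupby(["rat_id", "tissue"])[["vol_pred_mm3", "vol_ref_mm3"]].sum().reset_index()
    report.volume_p = {
        t: volume_comparison_test(
            rat_vols.loc[rat_vols.tissue == t, "vol_pred_mm3"].to_numpy(),
            rat_vols.loc[rat_vols.tissue == t, "vol_ref_mm3"].to_numpy(),
        )
        for t in TISSUES
    }
    report.meta["rat_volumes"] = rat_vols.to_dict(orient="records")

    if include_single_level:
        single_cat = np.concatenate(all_single)
        report.single_level = {
            "hemisphere_accuracy_pct": 100.0 * float(np.mean(single_cat == truth_cat)),
            "sensitivity_ic": confusion_metrics(single_cat, truth_cat, LABEL_IC)["sensitivity"],
            "sensitivity_ip": confusion_metrics(single_cat, truth_cat, LABEL_IP)["sensitivity"],
            "sensitivity_nt": confusion_metrics(single_cat, truth_cat, LABEL_NT)["sensitivity"],
        }
        report.pooled["sensitivity_ip_two_level"] = confusion_metrics(pred_cat, truth_cat, LABEL_IP)["sensitivity"]
    return report


def _pooled_metrics(pred: np.ndarray, truth: np.ndarray, s1: np.ndarray, s2: np.ndarray) -> dict:
    ic = confusion_metrics(pred, truth, LABEL_IC)
    ic["auc"] = roc_auc(s1, (truth == LABEL_IC).astype(int))
    non_ic = (truth != LABEL_IC) & (pred != LABEL_IC)
    if non_ic.any():
        ipnt = confusion_metrics(pred[non_ic], truth[non_ic], LABEL_IP)
        ipnt["auc"] = roc_auc(s2[non_ic], (truth[non_ic] == LABEL_IP).astype(int))
    else:
        ipnt = {"accuracy_pct": np.nan, "sensitivity": np.nan, "specificity": np.nan, "auc": np.nan}
    return {
        "ic_vs_nonic": ic,
        "ip_vs_nt": ipnt,
        "hemisphere_accuracy_pct": 100.0 * float(np.mean(pred == truth)),
        "n_voxels": int(pred.size),
    }


def kfold_cv_report(
    train: pd.DataFrame, backend: str = "svm", seed: int = 0, k: int = 5
) -> list[dict]:
    """Voxel-level stratified k-fold metrics on the pooled training data.

    This is the within-training estimate (guarding against overfitting);
    held-out generalisation comes from :func:`run_loocv`.
    """
    train = train.reset_index(drop=True)
    folds = kfold_split(train["label"].to_numpy(), k=k, seed=seed)
    out = []
    for i, (tr_idx, va_idx) in enumerate(folds):
        model = train_two_level(train.iloc[tr_idx], backend=backend, seed=seed)
        pred = predict_two_level(model, train.iloc[va_idx].reset_index(drop=True))
        fold = _fold_metrics(train.iloc[va_idx].reset_index(drop=True), pred)
        fold["fold"] = i
        out.append(fold)
    return out
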