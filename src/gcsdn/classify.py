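"""Identifying strategic deceivers from neural features.

Three linear-kernel SVMs (regularization C = 10) classify strategists versus
everyone else under leave-one-out cross-validation, taking as input the five
ROI activation indices, the twenty directed connectivity values, or both.
Decision scores are calibrated to probabilities by a logistic (Platt-style)
fit within each training fold; the added value of connectivity over
activation alone is quantified by ROC/AUC, the continuous net reclassification
improvement (NRI) and the integrated discrimination improvement (IDI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "FeatureSet",
    "ClassificationReport",
    "loo_svm",
    "roc_auc",
    "nri",
    "idi",
    "build_feature_sets",
]

FEATURE_KINDS = {"activation5": 5, "connectivity20": 20, "combined25": 25}


@dataclass(frozen=True)
class FeatureSet:
    """A subjects x features matrix with named columns."""

    kind: str
    matrix: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind in FEATURE_KINDS and self.matrix.shape[1] != FEATURE_KINDS[self.kind]:
            raise ValueError(
                f"{self.kind} expects {FEATURE_KINDS[self.kind]} columns, "
                f"got {self.matrix.shape[1]}"
            )
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match matrix columns")


@dataclass
class ClassificationReport:
    kind: str
    loo_predictions: np.ndarray  # 0/1 per subject
    decision_scores: np.ndarray  # SVM margins, one per held-out subject
    probabilities: np.ndarray  # Platt-calibrated per held-out subject
    accuracy: float
    roc_points: np.ndarray  # (n_thresholds, 2): (FPR, TPR)
    auc: float
    # comparison fields, filled when compared against a reference model
    nri: float = math.nan
    nri_z: float = math.nan
    nri_p: float = math.nan
    idi: float = math.nan
    idi_z: float = math.nan
    idi_p: float = math.nan


def _prepare_fold(train_x: np.ndarray, test_x: np.ndarray):
    """Train-fold standardization with train-fold mean imputation of NaNs."""
    col_mean = np.nanmean(train_x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    tr = np.where(np.isfinite(train_x), train_x, col_mean)
    te = np.where(np.isfinite(test_x), test_x, col_mean)
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (tr - mu) / sd, (te - mu) / sd


def loo_svm(
    features: FeatureSet,
    labels: Sequence[int],
    cost: float = 10.0,
) -> ClassificationReport:
    """Leave-one-out linear-kernel SVM.

    For each subject the model trains on the remaining n-1 (features
    standardized and NaNs mean-imputed within the training fold) and predicts
    the held-out one; accuracy is the mean correctness over the n folds.  A
    logistic calibration of the training-fold decision scores supplies a
    probability for the held-out subject.
    """
    y = np.asarray(labels, dtype=int)
    x = np.asarray(features.matrix, dtype=float)
    n = len(y)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 subjects per class")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("single-class training fold")
        tr, te = _prepare_fold(x[mask], x[i : i + 1])
        svm = SVC(kernel="linear", C=cost)
        svm.fit(tr, y[mask])
        preds[i] = int(svm.predict(te)[0])
        scores[i] = float(svm.decision_function(te)[0])
        train_scores = svm.decision_function(tr).reshape(-1, 1)
        platt = LogisticRegression(C=1e6)
        platt.fit(train_scores, y[mask])
        probs[i] = float(platt.predict_proba([[scores[i]]])[0, 1])
    accuracy = float((preds == y).mean())
    roc, auc = roc_auc(scores, y)
    return ClassificationReport(
        kind=features.kind,
        loo_predictions=preds,
        decision_scores=scores,
        probabilities=probs,
        accuracy=accuracy,
        roc_points=roc,
        auc=auc,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and AUC by the rank-sum identity.

    The AUC equals the probability that a random case outscores a random
    control, ties counted 1/2 (the Mann-Whitney statistic); the threshold
    sweep yields the same area, which the tests verify.  Constant scores give
    AUC 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # rank-sum AUC with tie correction
    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    points = []
    for th in thresholds:
        tpr = float(np.mean(pos >= th))
        fpr = float(np.mean(neg >= th))
        points.append((fpr, tpr))
    return np.array(points), auc


def nri(
    old_probs: Sequence[float], new_probs: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Category-free net reclassification improvement.

    Counts, among cases, the net fraction whose predicted probability moves up
    under the new model, plus, among controls, the net fraction moving down:
    ``NRI = [P(up|case) - P(down|case)] + [P(down|ctrl) - P(up|ctrl)]``.
    Returns (nri, z, two-sided p); zero movement in both classes yields
    (0, nan, 1).
    """
    old = np.asarray(old_probs, dtype=float)
    new = np.asarray(new_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(old) == len(new) == len(y)):
        raise ValueError("old, new and labels must align")
    case = y == 1
    ctrl = y == 0
    n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
    up_case = float(np.mean(new[case] > old[case]))
    down_case = float(np.mean(new[case] < old[case]))
    up_ctrl = float(np.mean(new[ctrl] > old[ctrl]))
    down_ctrl = float(np.mean(new[ctrl] < old[ctrl]))
    value = (up_case - down_case) + (down_ctrl - up_ctrl)
    var = (up_case + down_case) / n_case + (up_ctrl + down_ctrl) / n_ctrl
    if var == 0:
        return 0.0, math.nan, 1.0
    z = value / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(value), float(z), p


def idi(
    old_probs: Sequence[float], new_probs: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Integrated discrimination improvement.

    The gain in mean predicted-probability separation between cases and
    controls: ``(mean new|case - mean new|ctrl) - (mean old|case - mean
    old|ctrl)``.  The z-score combines the per-class SEs of the per-subject
    probability differences (cases and controls independent).
    """
    old = np.asarray(old_probs, dtype=float)
    new = np.asarray(new_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((old < 0) | (old > 1) | (new < 0) | (new > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    case = y == 1
    ctrl = y == 0
    d = new - old
    value = float(d[case].mean() - d[ctrl].mean())
    se_case = float(d[case].std(ddof=1)) / math.sqrt(case.sum()) if case.sum() > 1 else 0.0
    se_ctrl = float(d[ctrl].std(ddof=1)) / math.sqrt(ctrl.sum()) if ctrl.sum() > 1 else 0.0
    se = math.hypot(se_case, se_ctrl)
    if se == 0:
        return value, math.nan, 1.0 if value == 0 else 0.0
    z = value / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return value, float(z), p


def build_feature_sets(
    activations: Sequence,  # ActivationIndex per subject
    matrices: Sequence,  # CausalityMatrix per subject
    regions: Sequence[str],
) -> dict[str, FeatureSet]:
    """Assemble the activation-5, connectivity-20 and combined-25 matrices."""
    from .arbekk import direction_order

    act = np.array([[a.values[r] for r in regions] for a in activations])
    dirs = direction_order(regions)
    con = np.array([[m.f[d] for d in dirs] for m in matrices])
    act_names = tuple(f"act_{r}" for r in regions)
    con_names = tuple(f"F_{d}->{t}" for d, t in dirs)
    return {
        "activation5": FeatureSet("activation5", act, act_names),
        "connectivity20": FeatureSet("connectivity20", con, con_names),
        "combined25": FeatureSet(
            "combined25", np.hstack([act, con]), act_names + con_names
        ),
    }
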