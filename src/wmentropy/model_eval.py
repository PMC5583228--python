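"""Classification and regression evaluation of the entropy feature.

High/low performers are separated with a linear-kernel SVM on the selected
channel's spectral entropy; SRT scores are predicted with an RBF-kernel SVR.
Both are evaluated by leave-one-out cross-validation (intra-session) and by
training on one full session and testing on the other (inter-session).

Protocol details that matter for honesty at n = 20:

* standardization (feature, and the SVR target) is computed from the
  training fold only and applied to the held-out sample — no test statistic
  leaks into training;
* the SVM uses balanced class weights: leave-one-out folds are imbalanced
  by construction (removing a sample tilts the class ratio against its own
  class), and an unweighted margin classifier then votes with the majority,
  biasing null accuracy well below chance level;
* the ROC pools held-out decision scores across folds into a single curve;
  AUC is the trapezoidal area (equivalently the normalized Mann-Whitney U);
* no hyperparameter search: C, epsilon and gamma are fixed, configurable
  constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.svm import SVC, SVR

from .errors import (
    DegenerateFoldError,
    DegenerateTargetError,
    EmptyInputError,
    UndefinedAUCError,
    UnsupportedInputError,
)

POSITIVE = "high"  # high performers are the positive class
NEGATIVE = "low"


@dataclass
class SVMConfig:
    C: float = 1.0
    class_weight: str = "balanced"  # None reproduces the unweighted SVM


@dataclass
class SVRConfig:
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float = None  # None -> 1 / variance of the standardized training
    # feature (= 1.0 up to the ddof convention)


@dataclass
class ClassificationReport:
    scheme: str
    ca: float
    se: float
    sp: float
    auc: float
    predictions: pd.DataFrame  # subject, label, predicted, score
    counts: dict  # tp, tn, fp, fn

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "ca": self.ca,
            "se": self.se,
            "sp": self.sp,
            "auc": self.auc,
            "counts": self.counts,
            "predictions": self.predictions.to_dict("records"),
        }


@dataclass
class RegressionReport:
    scope: str
    rmsep: float
    r: float
    p: float
    predictions: pd.DataFrame  # subject, session, actual, predicted
    q: float = field(default=np.nan)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "rmsep": self.rmsep,
            "r": self.r,
            "p": self.p,
            "q": self.q,
            "predictions": self.predictions.to_dict("records"),
        }


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple:
    """(CA, SE, SP) from confusion counts; undefined ratios become NaN."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise UnsupportedInputError(f"count {name} must be >= 0, got {v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise UnsupportedInputError("confusion_metrics: empty table")
    ca = (tp + tn) / total
    se = tp / (tp + fn) if (tp + fn) > 0 else _undefined("sensitivity")
    sp = tn / (tn + fp) if (tn + fp) > 0 else _undefined("specificity")
    return ca, se, sp


def _undefined(metric: str) -> float:
    warnings.warn(f"{metric} undefined (empty class); reporting NaN")
    return float("nan")


def roc_auc(scores, labels) -> tuple:
    """ROC staircase and trapezoidal AUC from decision scores.

    ``labels`` are "high"/"low" (high = positive).  Returns
    ``(points, auc)`` where points is an array of (fpr, tpr) rows.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("ROC/AUC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(skmetrics.auc(fpr, tpr))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple:
    mu, sd = train.mean(), train.std(ddof=1)
    if sd == 0:
        raise DegenerateFoldError("zero feature variance in training fold")
    return (train - mu) / sd, (test - mu) / sd


def _fit_predict_svm(x_tr, y_tr, x_te, cfg: SVMConfig):
    if len(set(y_tr)) < 2:
        raise DegenerateFoldError("a class is absent from a training fold")
    clf = SVC(kernel="linear", C=cfg.C, class_weight=cfg.class_weight)
    clf.fit(x_tr.reshape(-1, 1), y_tr)
    pred = clf.predict(x_te.reshape(-1, 1))
    # orient the decision score so larger = more "high"
    score = clf.decision_function(x_te.reshape(-1, 1))
    if list(clf.classes_) == [POSITIVE, NEGATIVE]:
        score = -score
    return pred, score


def _report(scheme, subjects, labels, preds, scores) -> ClassificationReport:
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    tp = int(((preds == POSITIVE) & (labels == POSITIVE)).sum())
    tn = int(((preds == NEGATIVE) & (labels == NEGATIVE)).sum())
    fp = int(((preds == POSITIVE) & (labels == NEGATIVE)).sum())
    fn = int(((preds == NEGATIVE) & (labels == POSITIVE)).sum())
    ca, se, sp = confusion_metrics(tp, tn, fp, fn)
    try:
        _, auc = roc_auc(scores, labels)
    except UndefinedAUCError:
        auc = _undefined("AUC")
    return ClassificationReport(
        scheme=scheme,
        ca=ca,
        se=se,
        sp=sp,
        auc=auc,
        predictions=pd.DataFrame(
            {
                "subject": subjects,
                "label": labels,
                "predicted": preds,
                "score": np.asarray(scores, dtype=float),
            }
        ),
        counts={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def loocv_classify(
    features, labels, cfg: SVMConfig = None, subjects=None, scheme: str = "intra"
) -> ClassificationReport:
    """Leave-one-out SVM evaluation of a single feature.

    One fold per subject; the feature is standardized with the training
    fold's mean/sd only.  Pooled held-out predictions give CA/SE/SP and the
    pooled decision scores give one ROC/AUC.
    """
    cfg = cfg or SVMConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = x.size
    if n < 4 or min((y == POSITIVE).sum(), (y == NEGATIVE).sum()) < 2:
        raise DegenerateFoldError("need >= 2 subjects per class for LOOCV")
    subjects = np.arange(1, n + 1) if subjects is None else np.asarray(subjects)
    preds, scores = [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, x_te = _standardize(x[mask], x[i : i + 1])
        p, s = _fit_predict_svm(x_tr, y[mask], x_te, cfg)
        preds.append(p[0])
        scores.append(s[0])
    return _report(scheme, subjects, y, preds, scores)


def loocv_classify_nested(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    session: int,
    cfg: SVMConfig = None,
) -> ClassificationReport:
    """LOOCV with the feature channel re-selected inside each training fold.

    Selecting the best channel once on the whole cohort lets the selection
    see every subject, inflating downstream accuracy; this variant repeats
    the |Spearman r| selection on the 19 training subjects of every fold, so
    the held-out subject never influences which channel it is scored on.
    ``features`` is the full per-channel entropy table
    (``subject, session, channel, sen``), ``scores`` the grouped score table.
    """
    from .channels import fingerprint

    cfg = cfg or SVMConfig()
    feats = features[features["session"] == session]
    scs = scores[scores["session"] == session].sort_values("subject")
    subjects = scs["subject"].to_numpy()
    y = scs["group"].to_numpy()
    if min((y == POSITIVE).sum(), (y == NEGATIVE).sum()) < 2:
        raise DegenerateFoldError("need >= 2 subjects per class for LOOCV")
    wide = feats.pivot(index="subject", columns="channel", values="sen").loc[subjects]
    preds, dec_scores, channels = [], [], []
    for i, held_out in enumerate(subjects):
        train_subj = subjects[subjects != held_out]
        cmap = fingerprint(
            feats[feats["subject"].isin(train_subj)],
            scs[scs["subject"].isin(train_subj)],
            scope=f"session{session}",
        )
        ch = cmap.best_channel
        x = wide[ch].to_numpy()
        mask = subjects != held_out
        x_tr, x_te = _standardize(x[mask], x[i : i + 1])
        p, s = _fit_predict_svm(x_tr, y[mask], x_te, cfg)
        preds.append(p[0])
        dec_scores.append(s[0])
        channels.append(ch)
    report = _report(f"intra_s{session}_nested", subjects, y, preds, dec_scores)
    report.predictions["channel"] = channels
    return report


def cross_session_classify(
    train_features,
    train_labels,
    test_features,
    test_labels,
    cfg: SVMConfig = None,
    subjects=None,
    scheme: str = "inter",
) -> ClassificationReport:
    """Train on one full session, test once on the other."""
    cfg = cfg or SVMConfig()
    x_tr = np.asarray(train_features, dtype=float)
    x_te = np.asarray(test_features, dtype=float)
    if x_tr.size == 0 or x_te.size == 0:
        raise EmptyInputError("cross_session_classify: empty session")
    subjects = (
        np.arange(1, x_te.size + 1) if subjects is None else np.asarray(subjects)
    )
    x_tr_s, x_te_s = _standardize(x_tr, x_te)
    preds, scores = _fit_predict_svm(x_tr_s, np.asarray(train_labels), x_te_s, cfg)
    return _report(scheme, subjects, test_labels, preds, scores)


def loocv_svr(
    features,
    targets,
    cfg: SVRConfig = None,
    subjects=None,
    sessions=None,
    scope: str = "merged",
) -> RegressionReport:
    """Leave-one-out RBF-SVR prediction of SRT from the entropy feature.

    Feature and target are standardized per training fold; predictions are
    mapped back to score units.  Reports RMSEP over pooled held-out
    predictions and the Pearson correlation predicted-vs-actual.
    """
    cfg = cfg or SVRConfig()
    x = np.asarray(features, dtype=float)
    t = np.asarray(targets, dtype=float)
    n = x.size
    if n < 3:
        raise EmptyInputError(f"loocv_svr needs >= 3 subjects, got {n}")
    if t.std(ddof=1) == 0:
        raise DegenerateTargetError("zero target variance")
    subjects = np.arange(1, n + 1) if subjects is None else np.asarray(subjects)
    sessions = np.ones(n, dtype=int) if sessions is None else np.asarray(sessions)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, x_te = _standardize(x[mask], x[i : i + 1])
        mu_t, sd_t = t[mask].mean(), t[mask].std(ddof=1)
        gamma = cfg.gamma if cfg.gamma is not None else 1.0 / x_tr.var(ddof=1)
        model = SVR(kernel="rbf", C=cfg.C, epsilon=cfg.epsilon, gamma=gamma)
        model.fit(x_tr.reshape(-1, 1), (t[mask] - mu_t) / sd_t)
        preds[i] = model.predict(x_te.reshape(-1, 1))[0] * sd_t + mu_t
    rmsep = float(np.sqrt(np.mean((preds - t) ** 2)))
    r, p = stats.pearsonr(preds, t)
    return RegressionReport(
        scope=scope,
        rmsep=rmsep,
        r=float(r),
        p=float(p),
        predictions=pd.DataFrame(
            {"subject": subjects, "session": sessions, "actual": t, "predicted": preds}
        ),
    )
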