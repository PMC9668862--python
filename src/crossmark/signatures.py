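"""Random-forest marker signatures: tuning, evaluation, transfer and LODO
validation, and disease-specificity screening.

The central object is :class:`SignatureClassifier`, a scikit-learn-compatible
estimator wrapping a random forest over a fixed, ordered genus list.  The two
forest hyperparameters follow the R randomForest naming used throughout the
CRC-microbiome literature: ``mtry`` (features tried per split) and ``ntree``
(number of trees), tuned by out-of-bag (OOB) error on a grid.

Evaluation reports AUC with a DeLong 95% confidence interval plus accuracy,
sensitivity, specificity and F-score (2PR/(P+R)) at probability threshold 0.5
with the carcinoma class positive.  Cross-cohort generalization is measured
two ways: study-to-study transfer (train on one cohort, test on each other)
and leave-one-dataset-out (LODO: train on the union of all other cohorts).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .profiles import CohortProfile, pool_profiles
from .differential import CONTRASTS


class SignatureClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over a fixed ordered genus list.

    Parameters
    ----------
    genera : list of str or None
        Feature names, in order.  When None, taken from the DataFrame passed
        to :meth:`fit`.
    mtry : int
        Features considered at each split (randomForest's ``mtry``).
    ntree : int
        Number of trees (randomForest's ``ntree``).
    random_state : int
        Seed for the forest.

    Attributes
    ----------
    genera_ : list of str
        Feature order fixed at fit time.
    classes_ : ndarray
        Class labels.
    forest_ : RandomForestClassifier
        The fitted forest.
    oob_error_ : float
        Out-of-bag misclassification rate of the fitted forest.
    """

    def __init__(self, genera=None, mtry: int = 1, ntree: int = 400, random_state: int = 0):
        self.genera = genera
        self.mtry = mtry
        self.ntree = ntree
        self.random_state = random_state

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        X, self.genera_ = self._coerce(X, fitting=True)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need two classes to fit")
        if self.mtry > X.shape[1]:
            raise ValueError(f"mtry={self.mtry} exceeds number of genera {X.shape[1]}")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.ntree,
            max_features=self.mtry,
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny forests: some samples never OOB
            self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.oob_error_ = 1.0 - float(self.forest_.oob_score_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X, _ = self._coerce(X, fitting=False)
        return self.forest_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X, _ = self._coerce(X, fitting=False)
        return self.forest_.predict(X)

    def _coerce(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            genera = list(self.genera) if self.genera is not None else (
                list(self.genera_) if not fitting else list(X.columns)
            )
            missing = [g for g in genera if g not in X.columns]
            if missing:
                raise KeyError(f"missing genus column(s): {missing}")
            return X[genera].to_numpy(dtype=float), genera
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        genera = (
            list(self.genera)
            if self.genera is not None
            else (list(getattr(self, "genera_", range(X.shape[1]))) if not fitting
                  else [f"f{j}" for j in range(X.shape[1])])
        )
        return X, genera


@dataclass
class SignatureModel:
    """A named, fitted signature: genus list + forest + tuning record."""

    name: str
    genera: list
    rf_params: dict  # {"mtry": int, "ntree": int}
    classifier: SignatureClassifier
    training_cohorts: list
    seed: int
    oob_grid: dict = field(default_factory=dict)  # (mtry, ntree) -> OOB error

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "SignatureModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class EvaluationReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    n_pos: int
    n_neg: int
    positive_class: str
    threshold: float = 0.5


@dataclass
class TransferMatrix:
    cohort_ids: list
    auc: pd.DataFrame  # train-row x test-column; diagonal = within-cohort CV
    lodo: pd.Series | None = None  # AUC per held-out cohort


# ---------------------------------------------------------------------------
# AUC and metrics
# ---------------------------------------------------------------------------


def rank_auc(scores_pos, scores_neg) -> float:
    """Probability a positive outscores a negative (ties count half) via
    midranks."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: one class is empty")
    r = stats.rankdata(np.concatenate([pos, neg]))
    m, n = len(pos), len(neg)
    return float((r[:m].sum() - m * (m + 1) / 2) / (m * n))


def delong_ci(scores_pos, scores_neg, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong (midrank) confidence interval, clipped to [0, 1]."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def confusion_metrics(sensitivity: float, specificity: float, n_pos: int, n_neg: int) -> dict:
    """Reconstruct accuracy/precision/recall/F from reported sensitivity,
    specificity and class sizes (counts recovered by rounding)."""
    for v, name in ((sensitivity, "sensitivity"), (specificity, "specificity")):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} outside [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    fp = n_neg - tn
    fn = n_pos - tp
    if tp + fp == 0:
        raise ValueError("no predicted positives: precision undefined")
    recall = tp / n_pos
    precision = tp / (tp + fp)
    accuracy = (tp + tn) / (n_pos + n_neg)
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_score": f_score,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


# ---------------------------------------------------------------------------
# Fitting and evaluation on profiles
# ---------------------------------------------------------------------------


def _contrast_data(
    profile: CohortProfile, genera, contrast: str, impute_missing: bool = False
) -> tuple[pd.DataFrame, np.ndarray, str]:
    case, control = CONTRASTS[contrast]
    sub = profile.subset_groups([case, control])
    X = sub.abundance
    missing = [g for g in genera if g not in X.columns]
    if missing:
        if not impute_missing:
            raise KeyError(f"missing genus column(s): {missing}")
        warnings.warn(f"imputing absent genera as 0: {missing}")
    X = X.reindex(columns=list(genera), fill_value=0.0)
    y = sub.groups().to_numpy()
    return X, y, case


def tune_rf(
    profile: CohortProfile,
    genera,
    contrast: str = "CRC_vs_HC",
    mtry_grid=None,
    ntree_grid=None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Grid-search (mtry, ntree) by OOB error on the training cohort.

    Returns (best params, full OOB grid).  Ties break toward smaller ntree,
    then smaller mtry.  Grid points with mtry > |genera| are skipped with a
    warning.
    """
    genera = list(genera)
    if mtry_grid is None:
        mtry_grid = list(range(1, len(genera) + 1))
    if ntree_grid is None:
        ntree_grid = list(range(100, 1001, 100))
    if not mtry_grid or not ntree_grid:
        raise ValueError("empty tuning grid")
    X, y, _ = _contrast_data(profile, genera, contrast)
    grid: dict[tuple[int, int], float] = {}
    best = None
    for ntree in sorted(ntree_grid):
        for mtry in sorted(mtry_grid):
            if mtry > len(genera):
                warnings.warn(f"skipping mtry={mtry} > {len(genera)} genera")
                continue
            clf = SignatureClassifier(genera, mtry=mtry, ntree=ntree, random_state=seed)
            clf.fit(X, y)
            err = clf.oob_error_
            grid[(mtry, ntree)] = err
            key = (err, ntree, mtry)
            if best is None or key < best[0]:
                best = (key, {"mtry": mtry, "ntree": ntree})
    if best is None:
        raise ValueError("no valid grid point")
    return best[1], grid


def fit_signature(
    train: CohortProfile | list[CohortProfile],
    genera,
    rf_params: dict | None = None,
    contrast: str = "CRC_vs_HC",
    seed: int = 0,
    name: str = "signature",
    oob_grid: dict | None = None,
) -> SignatureModel:
    """Fit a named signature on one cohort or a pooled list of cohorts."""
    if isinstance(train, list):
        cohorts = [p.cohort_id for p in train]
        train = pool_profiles(train, taxa=None)
    else:
        cohorts = [train.cohort_id]
    rf_params = dict(rf_params or {"mtry": 1, "ntree": 400})
    genera = list(genera)
    X, y, _ = _contrast_data(train, genera, contrast)
    clf = SignatureClassifier(
        genera, mtry=rf_params["mtry"], ntree=rf_params["ntree"], random_state=seed
    )
    clf.fit(X, y)
    return SignatureModel(name, genera, rf_params, clf, cohorts, seed, oob_grid or {})


def _report_from_scores(scores, y, positive_class: str, threshold: float = 0.5) -> EvaluationReport:
    y = np.asarray(y)
    pos_mask = y == positive_class
    n_pos, n_neg = int(pos_mask.sum()), int((~pos_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: test set has a single class")
    scores = np.asarray(scores, dtype=float)
    auc, lo, hi = delong_ci(scores[pos_mask], scores[~pos_mask])
    pred_pos = scores >= threshold
    tp = int((pred_pos & pos_mask).sum())
    tn = int((~pred_pos & ~pos_mask).sum())
    fp = n_neg - tn
    sens = tp / n_pos
    spec = tn / n_neg
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    f = 2 * precision * sens / (precision + sens) if precision + sens > 0 else 0.0
    return EvaluationReport(
        auc=auc, auc_ci_low=lo, auc_ci_high=hi,
        accuracy=(tp + tn) / (n_pos + n_neg),
        sensitivity=sens, specificity=spec, f_score=f,
        n_pos=n_pos, n_neg=n_neg, positive_class=positive_class, threshold=threshold,
    )


def evaluate(
    model: SignatureModel,
    test: CohortProfile,
    contrast: str = "CRC_vs_HC",
    positive_class: str = "CRC",
    impute_missing: bool = False,
) -> EvaluationReport:
    """Evaluate a fitted signature on a test cohort.

    AUC is rank-based on predicted probabilities with a DeLong 95% CI; class
    metrics use probability threshold 0.5 with the carcinoma class positive.
    """
    X, y, _ = _contrast_data(test, model.genera, contrast, impute_missing=impute_missing)
    cls = list(model.classifier.classes_)
    proba = model.classifier.predict_proba(X)[:, cls.index(positive_class)]
    return _report_from_scores(proba, y, positive_class)


def roc_points(model: SignatureModel, test: CohortProfile,
               contrast: str = "CRC_vs_HC", positive_class: str = "CRC") -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for a fitted signature on a
    test cohort; write with ``.to_csv(path, sep="\\t")`` for TSV export."""
    from sklearn.metrics import roc_curve

    X, y, _ = _contrast_data(test, model.genera, contrast)
    cls = list(model.classifier.classes_)
    scores = model.classifier.predict_proba(X)[:, cls.index(positive_class)]
    fpr, tpr, thr = roc_curve(y == positive_class, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _cv_auc(profile: CohortProfile, genera, contrast, rf_params, seed, k: int = 5) -> float:
    """Within-cohort stratified k-fold CV AUC on pooled out-of-fold scores."""
    X, y, case = _contrast_data(profile, genera, contrast)
    min_class = min(np.bincount(pd.factorize(y)[0]))
    k = max(2, min(k, min_class))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    Xv = X.to_numpy(dtype=float)
    for tr, te in skf.split(Xv, y):
        clf = SignatureClassifier(
            list(genera), mtry=rf_params["mtry"], ntree=rf_params["ntree"], random_state=seed
        )
        clf.fit(Xv[tr], y[tr])
        cls = list(clf.classes_)
        scores[te] = clf.predict_proba(Xv[te])[:, cls.index(case)]
    mask = y == case
    return rank_auc(scores[mask], scores[~mask])


def _has_both_classes(profile: CohortProfile, contrast: str) -> bool:
    case, control = CONTRASTS[contrast]
    g = profile.groups()
    return (g == case).sum() >= 2 and (g == control).sum() >= 2


def transfer_validation(
    profiles: list[CohortProfile],
    genera,
    contrast: str = "CRC_vs_HC",
    rf_params: dict | None = None,
    seed: int = 0,
) -> TransferMatrix:
    """Study-to-study transfer: train on each cohort, test on every other.

    Off-diagonal (r, c) is the AUC of the model trained on cohort r applied
    to cohort c; the diagonal is within-cohort 5-fold stratified CV AUC.
    Cohorts lacking a contrast class are marked missing with a warning.
    """
    rf_params = dict(rf_params or {"mtry": 1, "ntree": 400})
    ids = [p.cohort_id for p in profiles]
    if len(ids) < 2:
        raise ValueError("need >=2 cohorts")
    ok = {}
    for p in profiles:
        ok[p.cohort_id] = _has_both_classes(p, contrast)
        if not ok[p.cohort_id]:
            warnings.warn(f"cohort {p.cohort_id} lacks a {contrast} class; marked missing")
    auc = pd.DataFrame(np.nan, index=ids, columns=ids)
    case = CONTRASTS[contrast][0]
    for p in profiles:
        if not ok[p.cohort_id]:
            continue
        model = fit_signature(p, genera, rf_params, contrast, seed, name=f"transfer-{p.cohort_id}")
        for q in profiles:
            if not ok[q.cohort_id]:
                continue
            if q.cohort_id == p.cohort_id:
                auc.loc[p.cohort_id, q.cohort_id] = _cv_auc(p, genera, contrast, rf_params, seed)
            else:
                auc.loc[p.cohort_id, q.cohort_id] = evaluate(
                    model, q, contrast, positive_class=case
                ).auc
    return TransferMatrix(ids, auc)


def lodo_validation(
    profiles: list[CohortProfile],
    genera,
    contrast: str = "CRC_vs_HC",
    rf_params: dict | None = None,
    seed: int = 0,
) -> pd.Series:
    """Leave-one-dataset-out: train on the union of all other cohorts, test on
    the held-out one.  Returns AUC per held-out cohort (NaN when the held-out
    cohort lacks a class)."""
    if len(profiles) < 3:
        raise ValueError("LODO needs >=3 cohorts")
    rf_params = dict(rf_params or {"mtry": 1, "ntree": 400})
    case = CONTRASTS[contrast][0]
    out = {}
    for i, held in enumerate(profiles):
        if not _has_both_classes(held, contrast):
            warnings.warn(f"held-out cohort {held.cohort_id} lacks a class; missing")
            out[held.cohort_id] = np.nan
            continue
        train = [p for j, p in enumerate(profiles) if j != i]
        model = fit_signature(train, genera, rf_params, contrast, seed, name=f"lodo-{held.cohort_id}")
        out[held.cohort_id] = evaluate(model, held, contrast, positive_class=case).auc
    return pd.Series(out, name="lodo_auc")


def specificity_screen(
    model: SignatureModel,
    disease_profiles: list[CohortProfile],
    positive_group: str = "disease",
    control_group: str = "control",
) -> pd.Series:
    """Apply a fitted CRC signature to other-disease cohorts.

    Each profile has groups {control, disease}; the returned AUC per disease
    set measures how strongly the CRC model reacts to that disease — values
    near 0.5 indicate the signature is CRC-specific.  Genera missing from a
    disease table are imputed as zero with a warning.
    """
    out = {}
    for p in disease_profiles:
        g = p.groups()
        sub_idx = g[g.isin([positive_group, control_group])].index
        X = p.abundance.loc[sub_idx]
        missing = [gn for gn in model.genera if gn not in X.columns]
        if missing:
            warnings.warn(
                f"{p.cohort_id}: {len(missing)} signature genera absent, imputed 0"
            )
        X = X.reindex(columns=model.genera, fill_value=0.0)
        y = g.loc[sub_idx].to_numpy()
        cls = list(model.classifier.classes_)
        crc_col = cls.index("CRC") if "CRC" in cls else 1
        scores = model.classifier.predict_proba(X)[:, crc_col]
        pos = y == positive_group
        out[p.cohort_id] = rank_auc(scores[pos], scores[~pos])
    return pd.Series(out, name="auc", dtype=float)
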