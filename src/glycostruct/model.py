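"""Random-forest site classifier, performance metrics and threshold
calibration for high-specificity screening.

AUC is computed by the rank (Mann-Whitney) statistic with ties averaged:
the probability that a random positive outscores a random negative. The
decision rule is ``score >= threshold``; the screening threshold is the
smallest score cut achieving a target specificity (default 0.99) on
negative calibration scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .types import SiteRecord


def mannwhitney_auc(y, scores) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties averaged)."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """The six scalar performance measures plus the ROC curve."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    auc: float
    roc: np.ndarray  # (n_points, 2) columns FPR, TPR
    threshold: float

    def to_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "accuracy": self.accuracy,
            "mcc": self.mcc, "auc": self.auc, "threshold": self.threshold,
        }


def compute_metrics(y, scores, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix measures at ``score >= threshold`` plus ROC/AUC.

    MCC uses the convention that a zero denominator factor gives MCC = 0;
    precision is 0 when nothing is called positive.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / y.size
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0
    auc = mannwhitney_auc(y, scores)
    fpr, tpr, _ = roc_curve(y, scores)
    roc = np.column_stack([fpr, tpr])
    if not np.allclose(roc[0], (0.0, 0.0)):
        roc = np.vstack([[0.0, 0.0], roc])
    if not np.allclose(roc[-1], (1.0, 1.0)):
        roc = np.vstack([roc, [1.0, 1.0]])
    return MetricsReport(sn, sp, pre, acc, float(mcc), auc, roc, threshold)


class GlycoSiteClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest classifier over named site feature vectors.

    A fitted model remembers its feature names and refuses feature matrices
    whose columns differ in name or order. ``decision_threshold_`` starts at
    0.5 and can be calibrated to a target specificity with
    :meth:`calibrate_threshold`.
    """

    def __init__(self, n_trees: int = 500, max_features: str | float = "sqrt",
                 glyco_type: str = "N", random_state: int | None = None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.glyco_type = glyco_type
        self.random_state = random_state

    def fit(self, X, y) -> "GlycoSiteClassifier":
        X = self._check_frame(X, fitting=True)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to train")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features=self.max_features,
            random_state=self.random_state, n_jobs=1)
        self.forest_.fit(X.to_numpy(dtype=float), y)
        self.classes_ = self.forest_.classes_
        self.decision_threshold_ = 0.5
        return self

    def _check_frame(self, X, fitting: bool = False) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"f{j}" for j in range(X.shape[1])] if fitting \
                else list(self.feature_names_)
        if fitting:
            self.feature_names_ = [str(c) for c in X.columns]
            return X
        if [str(c) for c in X.columns] != self.feature_names_:
            raise ValueError("feature names/order differ from the trained model")
        return X

    def predict_scores(self, X) -> np.ndarray:
        """Positive-class vote fraction per site, in [0, 1]."""
        X = self._check_frame(X)
        pos = list(self.classes_).index(1)
        return self.forest_.predict_proba(X.to_numpy(dtype=float))[:, pos]

    predict_proba_positive = predict_scores

    def predict(self, X, threshold: float | None = None) -> np.ndarray:
        t = self.decision_threshold_ if threshold is None else threshold
        return (self.predict_scores(X) >= t).astype(int)

    def calibrate_threshold(self, negative_scores, target_sp: float = 0.99) -> float:
        """Set and return the screening threshold (see
        :func:`threshold_at_specificity`)."""
        t, _ = threshold_at_specificity(negative_scores, target_sp)
        self.decision_threshold_ = t
        return t


def train_rf(X, y, feature_names: list[str] | None = None, n_trees: int = 500,
             seed: int | None = None, glyco_type: str = "N") -> GlycoSiteClassifier:
    """Train a :class:`GlycoSiteClassifier` (restricting to
    ``feature_names`` columns when given)."""
    if feature_names is not None:
        X = X[feature_names] if isinstance(X, pd.DataFrame) else \
            pd.DataFrame(np.asarray(X), columns=feature_names)
    return GlycoSiteClassifier(n_trees=n_trees, random_state=seed,
                               glyco_type=glyco_type).fit(X, y)


def predict_scores(model: GlycoSiteClassifier, X) -> np.ndarray:
    return model.predict_scores(X)


def threshold_at_specificity(negative_scores, target_sp: float = 0.99) -> tuple[float, float]:
    """Smallest threshold t with fraction(negatives scoring < t) >= target.

    Candidates are the distinct negative scores (plus a value just above
    the maximum); returns (threshold, achieved specificity).
    """
    s = np.asarray(negative_scores, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one negative score")
    if not 0.0 <= target_sp <= 1.0:
        raise ValueError("target specificity must be in [0, 1]")
    candidates = np.concatenate([np.unique(s), [np.nextafter(s.max(), np.inf)]])
    counts = np.searchsorted(np.sort(s), candidates, side="left")
    spec = counts / s.size
    ok = np.flatnonzero(spec >= target_sp)
    t = float(candidates[ok[0]])
    return t, float(spec[ok[0]])


def cross_validate(X, y, feature_names: list[str] | None = None, folds: int = 5,
                   rounds: int = 20, seed: int | None = None, n_trees: int = 100,
                   threshold: float = 0.5) -> tuple[list[MetricsReport], MetricsReport]:
    """Repeated stratified k-fold cross-validation.

    Out-of-fold scores are pooled within each round; one report per round
    plus the across-round mean report (its ROC taken from the last round).
    """
    Xf = X[feature_names] if feature_names is not None else X
    if not isinstance(Xf, pd.DataFrame):
        Xf = pd.DataFrame(np.asarray(Xf))
    arr = Xf.to_numpy(dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    reports: list[MetricsReport] = []
    for _ in range(rounds):
        fold_seed = int(rng.integers(2**31 - 1))
        rf_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        scores = np.empty(len(y))
        for train, test in skf.split(arr, y):
            rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                        random_state=rf_seed, n_jobs=1)
            rf.fit(arr[train], y[train])
            pos = list(rf.classes_).index(1)
            scores[test] = rf.predict_proba(arr[test])[:, pos]
        reports.append(compute_metrics(y, scores, threshold))
    mean = MetricsReport(
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
        roc=reports[-1].roc,
        threshold=threshold,
    )
    return reports, mean


def screen(model: GlycoSiteClassifier, X, sites: list[SiteRecord],
           author_numbers: dict[tuple[str, str, int], str] | None = None,
           threshold: float | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Score candidate sites and call those at or above the threshold.

    Returns the per-site prediction table (structure_id, chain, residue in
    author numbering when available, score, call, sequon flag) and the
    per-structure count of called sites.
    """
    t = model.decision_threshold_ if threshold is None else threshold
    if len(sites) == 0:
        empty = pd.DataFrame(columns=["structure_id", "chain", "residue", "aa",
                                      "score", "call", "sequon"])
        return empty, pd.Series(dtype=int)
    scores = model.predict_scores(X)
    rows = []
    for site, s in zip(sites, scores):
        resid = (author_numbers or {}).get(site.site_id, str(site.seq_index + 1))
        rows.append((site.structure_id, site.chain, resid, site.aa,
                     float(s), bool(s >= t), site.sequon))
    table = pd.DataFrame(rows, columns=["structure_id", "chain", "residue",
                                        "aa", "score", "call", "sequon"])
    counts = table[table["call"]].groupby("structure_id").size()
    return table, counts
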