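"""Two-step feature selection.

Step 1 ranks features by the absolute weights |w_j| of a linear soft-margin
SVM (w = sum_i alpha_i y_i x_i over support vectors) fitted on z-scored
features; the top-k (default 300) ranked names are the optimal feature
candidates (OFCs). Step 2 is incremental feature selection (IFS): growing
prefixes of the OFC list are evaluated by the mean AUC of a random-forest
classifier under repeated stratified 5-fold cross-validation (default 20
rounds), and the AUC-maximal prefix is the optimal feature set (OFS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .model import mannwhitney_auc


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


class SVMFeatureRanker(BaseEstimator):
    """Rank features by linear-SVM weight magnitude.

    Features are z-scored before fitting so weights are comparable across
    scales; zero-variance features are assigned weight 0 by convention.
    Ties in |w_j| break by original column order.

    Attributes (after ``fit``): ``weights_`` (|w_j| aligned to input
    columns), ``ranking_`` (feature names by descending weight) and
    ``feature_names_in_``.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y) -> "SVMFeatureRanker":
        X = _as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need two classes to rank features")
        arr = X.to_numpy(dtype=float)
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0)
        nonconst = sd > 0
        Z = np.zeros_like(arr)
        Z[:, nonconst] = (arr[:, nonconst] - mu[nonconst]) / sd[nonconst]
        svm = SVC(kernel="linear", C=self.C)
        svm.fit(Z[:, nonconst], y)
        w = np.zeros(arr.shape[1])
        w[nonconst] = np.abs(svm.coef_.ravel())
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.weights_ = w
        order = np.argsort(-w, kind="stable")
        self.ranking_ = [str(self.feature_names_in_[j]) for j in order]
        return self

    def top_k(self, k: int = 300) -> list[str]:
        """The first min(k, n_features) ranked feature names (the OFCs)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        return self.ranking_[: min(k, len(self.ranking_))]


@dataclass
class IFSResult:
    """Outcome of incremental feature selection."""

    ofc: list[str]
    auc_curve: np.ndarray
    auc_sd: np.ndarray
    ofs: list[str]
    folds: int
    rounds: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "prefix_size": np.arange(1, len(self.ofc) + 1),
            "feature": self.ofc,
            "mean_auc": self.auc_curve,
            "sd_auc": self.auc_sd,
        })


class IncrementalFeatureSelector(BaseEstimator):
    """Select the AUC-maximal prefix of an ordered candidate feature list.

    For each prefix size i, a random forest restricted to the first i
    candidates is evaluated by stratified k-fold cross-validation with
    out-of-fold scores pooled per round, repeated ``rounds`` times with
    freshly seeded fold shuffles and forest seeds; prefix AUCs are means
    over rounds. Ties resolve to the smallest prefix.

    Attributes (after ``fit``): ``auc_curve_``, ``auc_sd_``, ``ofs_``,
    ``result_`` (an :class:`IFSResult`).
    """

    def __init__(self, ofc: list[str] | None = None, folds: int = 5,
                 rounds: int = 20, n_trees: int = 100,
                 max_depth: int | None = None,
                 max_samples: float | None = None,
                 random_state: int | None = None):
        self.ofc = ofc
        self.folds = folds
        self.rounds = rounds
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_samples = max_samples
        self.random_state = random_state

    def fit(self, X, y) -> "IncrementalFeatureSelector":
        X = _as_frame(X)
        y = np.asarray(y).astype(int)
        ofc = list(self.ofc) if self.ofc is not None else [str(c) for c in X.columns]
        if not ofc:
            raise ValueError("empty candidate feature list")
        missing = [f for f in ofc if f not in X.columns]
        if missing:
            raise ValueError(f"candidate features absent from X: {missing[:5]}")
        arr = X[ofc].to_numpy(dtype=float)
        n = len(ofc)
        rng = np.random.default_rng(self.random_state)
        aucs = np.zeros((self.rounds, n))
        for r in range(self.rounds):
            fold_seed = int(rng.integers(2**31 - 1))
            rf_seed = int(rng.integers(2**31 - 1))
            skf = StratifiedKFold(n_splits=self.folds, shuffle=True,
                                  random_state=fold_seed)
            splits = list(skf.split(arr, y))
            for i in range(1, n + 1):
                scores = np.empty(len(y))
                for train, test in splits:
                    rf = RandomForestClassifier(
                        n_estimators=self.n_trees, max_features="sqrt",
                        max_depth=self.max_depth, max_samples=self.max_samples,
                        random_state=rf_seed, n_jobs=1)
                    rf.fit(arr[train, :i], y[train])
                    pos = list(rf.classes_).index(1)
                    scores[test] = rf.predict_proba(arr[test, :i])[:, pos]
                aucs[r, i - 1] = mannwhitney_auc(y, scores)
        mean_auc = aucs.mean(axis=0)
        sd_auc = aucs.std(axis=0)
        best = int(np.argmax(mean_auc))  # argmax takes the first (smallest) maximum
        self.auc_curve_ = mean_auc
        self.auc_sd_ = sd_auc
        self.ofs_ = ofc[: best + 1]
        self.result_ = IFSResult(ofc=ofc, auc_curve=mean_auc, auc_sd=sd_auc,
                                 ofs=self.ofs_, folds=self.folds,
                                 rounds=self.rounds, seed=self.random_state)
        return self

    def transform(self, X) -> pd.DataFrame:
        return _as_frame(X)[self.ofs_]


def svm_rank(X, y, C: float = 1.0) -> SVMFeatureRanker:
    """Fit and return a :class:`SVMFeatureRanker`."""
    return SVMFeatureRanker(C=C).fit(X, y)


def top_k(result: SVMFeatureRanker, k: int = 300) -> list[str]:
    """The top-k ranked feature names of a fitted ranker."""
    return result.top_k(k)


def incremental_feature_selection(X, y, ofc: list[str], folds: int = 5,
                                  rounds: int = 20, seed: int | None = None,
                                  n_trees: int = 100, max_depth: int | None = None,
                                  max_samples: float | None = None) -> IFSResult:
    """Run IFS over the ordered candidate list and return its result."""
    sel = IncrementalFeatureSelector(ofc=ofc, folds=folds, rounds=rounds,
                                     n_trees=n_trees, max_depth=max_depth,
                                     max_samples=max_samples, random_state=seed)
    sel.fit(X, y)
    return sel.result_
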