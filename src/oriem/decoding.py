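"""Backward decoding of presented orientation with diagonal naive Bayes.

The classifier is the 'diaglinear' Gaussian discriminant: class-conditional
Gaussians with a diagonal covariance pooled across classes (per-class
variances are available as the 'diagquadratic' variant), uniform priors,
argmax posterior.  Features are the same window-averaged sensor values the
encoder uses, so encoder/decoder comparisons are like-for-like.  Accuracy
at a time point is the fraction of held-out trials whose predicted
orientation equals the presented one; chance is 1/9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._utils import logger
from .design import expectation_of
from .encoding import _make_folds, _sliding_features
from .epochs import EpochsArray


class DiagonalNaiveBayes(BaseEstimator, ClassifierMixin):
    """Gaussian naive Bayes with pooled ('diaglinear') or per-class
    ('diagquadratic') diagonal covariance and uniform priors.

    Ties in the posterior are broken toward the lowest class index (logged).
    Zero-variance features are floored at ``var_floor`` with a logged note.
    """

    def __init__(self, var_mode: str = "pooled", var_floor: float = 1e-12):
        self.var_mode = var_mode
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("need at least 2 training examples per class")
        k, f = len(self.classes_), X.shape[1]
        self.theta_ = np.zeros((k, f))
        for c in range(k):
            self.theta_[c] = X[y_idx == c].mean(axis=0)
        if self.var_mode == "pooled":
            resid = X - self.theta_[y_idx]
            var = (resid**2).sum(axis=0) / (len(X) - k)
            self.var_ = np.tile(var, (k, 1))
        elif self.var_mode == "per_class":
            self.var_ = np.zeros((k, f))
            for c in range(k):
                self.var_[c] = X[y_idx == c].var(axis=0, ddof=1)
        else:
            raise ValueError(f"unknown var_mode {self.var_mode!r}")
        if np.any(self.var_ < self.var_floor):
            logger.info("zero-variance feature(s) floored at %g", self.var_floor)
            self.var_ = np.maximum(self.var_, self.var_floor)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        ll = np.empty((X.shape[0], len(self.classes_)))
        for c in range(len(self.classes_)):
            d = X - self.theta_[c]
            ll[:, c] = -0.5 * np.sum(d**2 / self.var_[c] + np.log(2 * np.pi * self.var_[c]),
                                     axis=1)
        return ll

    def predict_log_proba(self, X):
        ll = self._joint_log_likelihood(X)
        norm = np.logaddexp.reduce(ll, axis=1, keepdims=True)
        return ll - norm

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        ll = self._joint_log_likelihood(X)
        ties = (ll == ll.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            logger.info("%d posterior tie(s) broken toward lowest class index",
                        int(ties.sum()))
        return self.classes_[np.argmax(ll, axis=1)]


def nb_fit_predict(B_train, labels_train, B_test, var_mode: str = "pooled"):
    """Fit the diagonal naive Bayes and return (predicted labels, posteriors)."""
    clf = DiagonalNaiveBayes(var_mode=var_mode).fit(B_train, labels_train)
    return clf.predict(B_test), clf.predict_proba(B_test)


@dataclass
class DecodingResult:
    """Per-trial, per-time predicted orientations and derived accuracies."""

    times: np.ndarray
    predictions: np.ndarray     # (n_trials_used, n_times) predicted orientation
    labels: np.ndarray          # (n_trials_used,) presented orientation
    design: "object"            # DataFrame of the used trials
    n_classes: int = 9

    @property
    def correct(self) -> np.ndarray:
        return self.predictions == self.labels[:, None]

    def accuracy(self) -> np.ndarray:
        """Overall accuracy time course."""
        return self.correct.mean(axis=0)

    def accuracy_by(self, grouping: str) -> pd.DataFrame:
        if grouping == "expectation":
            labels = expectation_of(self.design["condition"].to_numpy())
        elif grouping == "repetition":
            labels = self.design["trial_type"].to_numpy()
        else:
            labels = self.design[grouping].to_numpy()
        out = {}
        for level in pd.unique(labels):
            out[level] = self.correct[labels == level].mean(axis=0)
        return pd.DataFrame(out, index=pd.Index(self.times, name="time"))


def decode_timecourse(
    epochs: EpochsArray,
    window_ms: float = 16.0,
    step_ms: float = 4.0,
    cv="kfold10",
    tmin: float = None,
    tmax: float = None,
    seed: int = 0,
    var_mode: str = "pooled",
) -> DecodingResult:
    """Cross-validated naive Bayes decoding at every time point.

    Training pools all conditions (per-condition scoring happens on the
    stored per-trial predictions); folds are the same stratified scheme the
    encoder uses.
    """
    used = epochs.retained()
    table = epochs.design.table.iloc[used].reset_index(drop=True)
    feats, centers = _sliding_features(epochs, window_ms, step_ms, tmin, tmax)
    feats = feats[used]
    labels = table["orientation_second"].to_numpy()
    folds = _make_folds(table, cv, seed)
    n_trials, n_feat, T = feats.shape
    preds = np.empty((n_trials, T), dtype=labels.dtype)
    classes = np.unique(labels)
    for train_idx, test_idx in folds:
        Xtr, Xte = feats[train_idx], feats[test_idx]
        ytr = labels[train_idx]
        k = len(classes)
        theta = np.zeros((k, n_feat, T))
        for c, cls in enumerate(classes):
            theta[c] = Xtr[ytr == cls].mean(axis=0)
        if var_mode == "pooled":
            cls_idx = np.searchsorted(classes, ytr)
            resid = Xtr - theta[cls_idx]
            var = (resid**2).sum(axis=0) / (len(Xtr) - k)      # (n_feat, T)
            var = np.maximum(var, 1e-12)
            mu_v = theta / var[None]                            # (k, f, T)
            t2 = np.einsum("nft,kft->nkt", Xte, mu_v, optimize=True)
            t3 = np.einsum("kft,kft->kt", theta, mu_v, optimize=True)
            ll = t2 - 0.5 * t3[None]
        else:
            var = np.zeros((k, n_feat, T))
            for c, cls in enumerate(classes):
                var[c] = Xtr[ytr == cls].var(axis=0, ddof=1)
            var = np.maximum(var, 1e-12)
            xv = np.einsum("nft,kft->nkt", Xte**2, 1.0 / var, optimize=True)
            xm = np.einsum("nft,kft->nkt", Xte, theta / var, optimize=True)
            mm = np.einsum("kft,kft->kt", theta, theta / var, optimize=True)
            lv = np.log(var).sum(axis=1)                        # (k, T)
            ll = -0.5 * (xv - 2 * xm + mm[None] + lv[None])
        preds[test_idx] = classes[np.argmax(ll, axis=1)]
    return DecodingResult(times=centers, predictions=preds, labels=labels,
                          design=table, n_classes=len(classes))


def peak_accuracy(
    result: DecodingResult,
    window: tuple[float, float] = (0.6, 1.2),
    grouping: str = None,
) -> pd.DataFrame:
    """Maximum accuracy within a window (default: 600 ms from second-Gabor
    onset), optionally per group level."""
    t = result.times
    sel = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"window {window} outside decoded time axis")
    if grouping is None:
        acc = result.accuracy()[sel]
        i = int(np.argmax(acc))
        return pd.DataFrame([{"group": "all", "peak_accuracy": float(acc[i]),
                              "peak_time": float(t[sel][i])}])
    accs = result.accuracy_by(grouping)
    rows = []
    for level in accs.columns:
        a = accs[level].to_numpy()[sel]
        i = int(np.argmax(a))
        rows.append({"group": level, "peak_accuracy": float(a[i]),
                     "peak_time": float(t[sel][i])})
    return pd.DataFrame(rows)
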