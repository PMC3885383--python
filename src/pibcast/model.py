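"""Pre-ictal vs inter-ictal classification.

Forward feature selection, ridge-stabilized logistic regression, and
out-of-fold risk prediction. Raw PIB values are heavy-tailed, so features
enter the classifier as ``log10(PIB + eps)`` standardized per feature with
statistics learned from the training folds only; risks are therefore
invariant to affine rescaling of the raw power values.

Forward selection is greedy on inner-validation AUC: within the training
data a nested contiguous split (5 folds by default) scores each candidate
feature set, and the feature giving the largest mean AUC is added until the
budget (10 of 96 by default) is reached. Ties break to the lowest column
index, which together with the deterministic solver makes the whole fit
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .core_io import RunConfig
from .features import FeatureMatrix, INTERICTAL, PREICTAL

logger = logging.getLogger("pibcast")

__all__ = ["LogisticModel", "RiskSeries", "fit_logistic", "forward_select",
           "cross_val_risk"]

#: guard added before the log so empty bands do not produce -inf
LOG_EPS = np.finfo(float).tiny


@dataclass
class LogisticModel:
    """A fitted pre-ictal classifier restricted to its selected features."""

    selected: np.ndarray          # column indices into the full feature set
    coef: np.ndarray              # one weight per selected feature
    intercept: float
    mu: np.ndarray                # per-feature log10 location (training data)
    sigma: np.ndarray             # per-feature log10 scale (training data)

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        Z = (np.log10(X_raw + LOG_EPS) - self.mu) / self.sigma
        return Z[:, self.selected]

    def predict_risk(self, X_raw: np.ndarray) -> np.ndarray:
        """Classifier output on a continuous scale in [0, 1]."""
        z = self.transform(X_raw) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.tolist(),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(np.array(d["selected"], dtype=int), np.array(d["coef"]),
                   float(d["intercept"]), np.array(d["mu"]), np.array(d["sigma"]))


@dataclass
class RiskSeries:
    """Out-of-fold per-block risks with fold provenance."""

    block_start_s: np.ndarray
    risk: np.ndarray
    fold: np.ndarray
    skipped_folds: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"block_start_s": self.block_start_s,
                             "risk": self.risk, "fold": self.fold})


def _log_standardize(X: np.ndarray):
    """Log10 transform + per-feature standardization statistics."""
    L = np.log10(X + LOG_EPS)
    mu = L.mean(axis=0)
    sigma = L.std(axis=0)
    sigma[sigma == 0] = 1.0
    return (L - mu) / sigma, mu, sigma


def fit_logistic(Z: np.ndarray, y: np.ndarray, ridge: float = 1e-4):
    """Ridge-penalized logistic regression on pre-scaled features.

    Returns ``(coef, intercept)``. ``ridge`` is the L2 penalty scale
    (sklearn ``C = 1/ridge``); the default is small enough to leave
    well-conditioned problems essentially unpenalized.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite feature values passed to fit_logistic")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_logistic requires both classes present")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000,
                             tol=1e-8)
    clf.fit(Z, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _inner_cv_auc(Z: np.ndarray, y: np.ndarray, cols: list[int],
                  bounds: np.ndarray, ridge: float) -> float:
    """Mean AUC over contiguous inner folds for the given feature columns."""
    aucs = []
    n = len(y)
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        test = np.zeros(n, dtype=bool)
        test[a:b] = True
        ytr, yte = y[~test], y[test]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            continue
        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=200)
        clf.fit(Z[~test][:, cols], ytr)
        score = clf.decision_function(Z[test][:, cols])
        aucs.append(roc_auc_score(yte, score))
    return float(np.mean(aucs)) if aucs else 0.5


def forward_select(Z: np.ndarray, y: np.ndarray, k: int,
                   n_inner_folds: int = 5, ridge: float = 1e-4) -> np.ndarray:
    """Greedy forward selection of k features maximizing inner-CV AUC.

    Rows must be in time order (the inner split is contiguous). Ties break
    to the lowest column index. Only the data passed in — i.e. training-fold
    rows — is ever touched.
    """
    n, p = Z.shape
    if k > p:
        raise ValueError(f"cannot select {k} of {p} features")
    bounds = np.linspace(0, n, n_inner_folds + 1).astype(int)
    selected: list[int] = []
    remaining = list(range(p))
    for _ in range(k):
        best_j, best_auc = None, -np.inf
        for j in remaining:
            auc = _inner_cv_auc(Z, y, selected + [j], bounds, ridge)
            if auc > best_auc + 1e-12:
                best_auc, best_j = auc, j
        selected.append(best_j)
        remaining.remove(best_j)
    return np.array(selected, dtype=int)


def fit_fold_model(X_raw: np.ndarray, y: np.ndarray, config: RunConfig) -> LogisticModel:
    """Scale, select and fit on one training split (rows in time order)."""
    Z, mu, sigma = _log_standardize(X_raw)
    k = min(config.n_features, X_raw.shape[1])
    selected = forward_select(Z, y, k, config.n_inner_folds, config.ridge)
    coef, intercept = fit_logistic(Z[:, selected], y, config.ridge)
    return LogisticModel(selected, coef, intercept, mu, sigma)


def cross_val_risk(fm: FeatureMatrix, config: RunConfig):
    """Out-of-fold risk prediction with per-fold selection and fitting.

    For each fold f the model (scaling, feature selection, weights) is
    learned on all other folds' labeled blocks and applied to fold f's
    valid non-ictal blocks; no test-fold row influences any part of the
    fit. Returns ``(RiskSeries, models, train_risks)`` where ``models``
    maps fold id -> :class:`LogisticModel` and ``train_risks`` maps fold
    id -> (block_start_s, risk) on that model's own training blocks (used
    downstream to calibrate warning thresholds without touching test data).

    A fold whose training split lacks pre-ictal blocks cannot be fit; its
    blocks carry NaN risk and the fold id is reported in
    ``RiskSeries.skipped_folds``.
    """
    labels = fm.labels
    fold = fm.fold
    if np.all(fold < 0):
        raise ValueError("folds not assigned; run make_folds first")
    usable = fm.valid & np.isin(labels, (INTERICTAL, PREICTAL))
    fold_ids = sorted(int(f) for f in np.unique(fold[fold >= 0]))

    risk = np.full(fm.n_blocks, np.nan)
    models: dict[int, LogisticModel] = {}
    train_risks: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    skipped: list[int] = []

    for f in fold_ids:
        train = usable & (fold != f) & (fold >= 0)
        test = usable & (fold == f)
        y_train = (labels[train] == PREICTAL).astype(int)
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %d: training split lacks both classes; skipped", f)
            skipped.append(f)
            continue
        model = fit_fold_model(fm.X[train], y_train, config)
        models[f] = model
        train_risks[f] = (fm.block_start_s[train], model.predict_risk(fm.X[train]))
        if test.any():
            risk[test] = model.predict_risk(fm.X[test])

    out = usable & np.isfinite(risk)
    series = RiskSeries(fm.block_start_s[out], risk[out], fold[out], skipped)
    return series, models, train_risks
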