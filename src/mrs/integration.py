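"""Late integration of per-omics risk scores.

Each omics layer is first summarized into a single risk score per sample;
an additive logistic regression then combines the (standardized) scores for
disease prediction.  The combined model is evaluated by cross-validation in
which every layer's score — including its own P+T feature selection — is
rebuilt on the training samples of each fold.  Spearman correlations between
the most frequently selected features of two layers describe cross-omics
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._exceptions import NumericalError, ValidationError
from .da_tests import run_da
from .evaluation import mann_whitney_auc, roc_auc
from .feature_io import FeatureTable
from .mrs_core import RiskScoreVector
from .pt_selection import (
    _resolve_folds,
    _subset_samples,
    candidate_thresholds,
    grid_score_matrix,
)

RIDGE_FALLBACK = 1e-4


@dataclass
class LogisticModel:
    score_names: list[str]
    intercept: float
    coefficients: np.ndarray
    converged: bool
    n_iterations: int
    ridge_penalty: float = 0.0

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        return expit(self.intercept + np.asarray(scores, float) @ self.coefficients)

    def to_dict(self) -> dict:
        return {
            "score_names": list(self.score_names),
            "intercept": float(self.intercept),
            "coefficients": [float(c) for c in self.coefficients],
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "ridge_penalty": self.ridge_penalty,
        }


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, tol: float, max_iter: int):
    n, m = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(m + 1)
    pen = np.zeros(m + 1)
    pen[1:] = ridge  # intercept unpenalized
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        A = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        b = (Xd * w[:, None]).T @ z
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            if ridge > 0:
                raise NumericalError("IRLS normal equations singular even under ridge")
            return beta, False, it  # singular design: let the ridge fallback handle it
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            return beta, True, it
        if np.max(np.abs(beta)) > 1e4:
            return beta, False, it  # diverging: separation
    return beta, False, max_iter


def fit_logistic_additive(
    scores: np.ndarray,
    labels,
    score_names: Optional[list[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    interactions: bool = False,
) -> LogisticModel:
    """Maximum-likelihood additive logistic fit by IRLS.

    On detected separation (diverging coefficients or non-convergence) the
    model is refit with a small ridge penalty (1e-4) on the slopes and the
    fallback is flagged via ``ridge_penalty``.  ``interactions=True`` adds
    all pairwise score products for risk-stratification exploration; the
    default model is purely additive.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if interactions and X.shape[1] > 1:
        names = score_names or [f"score_{j}" for j in range(X.shape[1])]
        cols, cross_names = [X], list(names)
        for a in range(X.shape[1]):
            for b in range(a + 1, X.shape[1]):
                cols.append((X[:, a] * X[:, b])[:, None])
                cross_names.append(f"{names[a]}*{names[b]}")
        X = np.hstack(cols)
        score_names = cross_names
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        raise ValidationError("scores and labels have different lengths")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValidationError("non-finite inputs to logistic fit")
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes are required")
    names = score_names or [f"score_{j}" for j in range(X.shape[1])]
    beta, converged, iters = _irls(X, y, 0.0, tol, max_iter)
    ridge = 0.0
    if not converged:
        beta, converged, iters = _irls(X, y, RIDGE_FALLBACK, tol, max_iter)
        ridge = RIDGE_FALLBACK
    return LogisticModel(names, float(beta[0]), beta[1:], converged, iters, ridge)


# ---------------------------------------------------------------------------
# per-omics score builders for cross-validated integration


def make_mrs_builder(
    table: FeatureTable,
    da_method: str = "wilcoxon",
    score_spec: str = "shannon",
    max_grid: int = 50,
) -> Callable:
    """Builder that re-runs DA + P+T on each training fold of a microbiome
    layer and emits (train, test) sub-community scores.

    The threshold is picked by training-sample AUC along the nested path
    (resubstitution selection inside the fold; the outer CV still measures
    honest held-out performance).
    """
    from .mrs_core import _as_relative

    rel = _as_relative(table)

    def builder(train_idx, test_idx, y_train):
        da = run_da(_subset_samples(table, train_idx), y_train, method=da_method)
        thresholds = candidate_thresholds(da, max_grid)
        w = da.effect if score_spec == "weighted_sum" else None
        tr_scores = grid_score_matrix(rel.values[:, train_idx], da.p_value,
                                      thresholds, score_spec, weights=w)
        aucs = np.array([mann_whitney_auc(tr_scores[t], y_train)
                         for t in range(thresholds.size)])
        nonempty = np.searchsorted(np.sort(da.p_value), thresholds, side="left") > 0
        if not nonempty.any():
            best = thresholds.size - 1
        else:
            m = aucs[nonempty].max()
            best = int(np.where(nonempty & np.isclose(aucs, m, atol=1e-12, rtol=0))[0][0])
        te_scores = grid_score_matrix(rel.values[:, test_idx], da.p_value,
                                      thresholds, score_spec, weights=w)
        return tr_scores[best], te_scores[best], {
            "threshold": float(thresholds[best]),
            "selected": [f for f, p in zip(da.feature_ids, da.p_value)
                         if p < thresholds[best]],
        }

    return builder


def make_signed_logcount_builder(table: FeatureTable, max_grid: int = 50) -> Callable:
    """Builder for a transcriptome-type layer: per-gene Welch t-test on
    ln(count+1), P+T over the p-value path, score = signed sum of log counts
    with sign = direction of the training fold change."""
    logx = np.log1p(table.values)

    def builder(train_idx, test_idx, y_train):
        a = logx[:, train_idx][:, y_train == 1]
        b = logx[:, train_idx][:, y_train == 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.nan_to_num(np.asarray(res.pvalue, float), nan=1.0)
        effect = a.mean(axis=1) - b.mean(axis=1)
        signs = np.where(effect >= 0, 1.0, -1.0)
        thresholds = np.append(np.unique(np.quantile(np.unique(p),
                                                     np.linspace(0, 1, max_grid))),
                               1.0 + 1e-6)
        tr_scores = grid_score_matrix(logx[:, train_idx], p, thresholds,
                                      "weighted_sum", weights=signs)
        aucs = np.array([mann_whitney_auc(tr_scores[t], y_train)
                         for t in range(thresholds.size)])
        nonempty = np.searchsorted(np.sort(p), thresholds, side="left") > 0
        if not nonempty.any():
            best = thresholds.size - 1
        else:
            m = aucs[nonempty].max()
            best = int(np.where(nonempty & np.isclose(aucs, m, atol=1e-12, rtol=0))[0][0])
        te_scores = grid_score_matrix(logx[:, test_idx], p, thresholds,
                                      "weighted_sum", weights=signs)
        return tr_scores[best], te_scores[best], {
            "threshold": float(thresholds[best]),
            "selected": [f for f, pv in zip(table.feature_ids, p)
                         if pv < thresholds[best]],
        }

    return builder


def make_fixed_score_builder(scores: np.ndarray) -> Callable:
    """Builder wrapping a precomputed per-sample score (no refitting)."""
    x = np.asarray(scores, dtype=float)

    def builder(train_idx, test_idx, y_train):
        return x[train_idx], x[test_idx], {}

    return builder


def combined_cv_prediction(
    score_builders: list,
    labels,
    sample_ids: Optional[list[str]] = None,
    cv: str = "kfold",
    k: int = 5,
    seed: int = 17,
    score_names: Optional[list[str]] = None,
):
    """Cross-validated additive-logistic combination of per-omics scores.

    Within each fold every builder produces training and held-out scores from
    training data only; scores are standardized with training moments, the
    logistic combiner is fitted on the training scores, and held-out
    probabilities are pooled into a single predicted-probability vector.

    Returns ``(RiskScoreVector of probabilities, ROCSummary)``.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    folds, scheme = _resolve_folds(y, cv, k, seed)
    probs = np.zeros(n)
    m = len(score_builders)
    for tr, te in folds:
        Xtr = np.zeros((tr.size, m))
        Xte = np.zeros((te.size, m))
        for j, builder in enumerate(score_builders):
            s_tr, s_te, _ = builder(tr, te, y[tr])
            mu, sd = s_tr.mean(), s_tr.std(ddof=1)
            if sd == 0:
                sd = 1.0
            Xtr[:, j] = (s_tr - mu) / sd
            Xte[:, j] = (s_te - mu) / sd
        model = fit_logistic_additive(Xtr, y[tr], score_names=score_names)
        probs[te] = model.predict_proba(Xte)
    ids = sample_ids or [f"sample_{i}" for i in range(n)]
    vec = RiskScoreVector(ids, probs, "combined_probability", "signed_logcount",
                          orientation_note=f"additive logistic CV probabilities ({scheme})")
    return vec, roc_auc(probs, y)


def cross_omics_spearman(
    table_a: FeatureTable,
    table_b: FeatureTable,
    importance_a: np.ndarray,
    importance_b: np.ndarray,
    top_k: int = 50,
    effect_a: Optional[np.ndarray] = None,
    effect_b: Optional[np.ndarray] = None,
    groups=None,
):
    """Spearman correlation matrix between each layer's top features.

    Features are ranked by selection proportion across CV folds, ties broken
    by absolute effect size.  With a per-sample ``groups`` vector a matrix is
    returned per group level (dict), otherwise a single DataFrame.
    """
    if table_a.sample_ids != table_b.sample_ids:
        raise ValidationError("tables must share identical samples (same order)")

    def _top(table, imp, eff):
        imp = np.asarray(imp, float)
        if imp.shape != (table.n_features,):
            raise ValidationError("importance length does not match features")
        tie = np.abs(np.asarray(eff, float)) if eff is not None else np.zeros_like(imp)
        order = np.lexsort((-tie, -imp))
        k = min(top_k, table.n_features)
        if top_k > table.n_features:
            import warnings

            warnings.warn(f"top_k clipped to {table.n_features}")
        return order[:k]

    ia = _top(table_a, importance_a, effect_a)
    ib = _top(table_b, importance_b, effect_b)
    names_a = [table_a.feature_ids[i] for i in ia]
    names_b = [table_b.feature_ids[i] for i in ib]

    def _matrix(mask):
        a = table_a.values[np.ix_(ia, np.where(mask)[0])]
        b = table_b.values[np.ix_(ib, np.where(mask)[0])]
        rho = stats.spearmanr(np.vstack([a, b]).T).statistic
        block = np.atleast_2d(rho)[: len(ia), len(ia):]
        return pd.DataFrame(block, index=names_a, columns=names_b)

    if groups is None:
        return _matrix(np.ones(table_a.n_samples, bool))
    groups = np.asarray(groups)
    return {g: _matrix(groups == g) for g in np.unique(groups)}
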