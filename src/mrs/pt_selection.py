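"""Pruning-and-thresholding (P+T) sub-community selection under cross-validation.

A grid of candidate p-value cutoffs defines nested taxon sets ({p < t}).  For
every cross-validation fold, differential abundance is (by default) re-run on
the training samples only, and each threshold's training-derived sub-community
scores the held-out samples.  The cutoff maximizing the pooled held-out AUC is
chosen (ties broken toward the smallest cutoff, i.e. the fewest taxa), and the
final sub-community is the full-data DA result thresholded at that cutoff.

The grid itself is placed once from the full-data p-values — analogous to a
regularization path laid out before cross-validation — while per-fold set
membership at each grid value uses training-only p-values, so held-out samples
can never influence which taxa a fold selects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import special
from sklearn.model_selection import StratifiedKFold

from ._exceptions import SelectionError, ValidationError
from .da_tests import DAResult, run_da
from .evaluation import mann_whitney_auc
from .feature_io import FeatureTable
from .mrs_core import (
    ALPHA_INDICES,
    DEGENERATE_SCORE,
    RiskScoreVector,
    SubCommunity,
    _as_relative,
    mrs_alpha,
    mrs_standard,
)

TERMINAL_EPS = 1e-6

SCORE_SPECS = ALPHA_INDICES + ("unweighted_sum", "weighted_sum")


@dataclass
class PTResult:
    thresholds: np.ndarray
    cv_auc: np.ndarray
    chosen_threshold: float
    chosen_taxa: SubCommunity
    cv_scheme: str
    score_spec: str
    per_sample_cv_scores: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    selection_proportion: np.ndarray
    da_full: DAResult
    orientation_sign: int = 1

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(t) for t in self.thresholds],
            "cv_auc": [float(a) for a in self.cv_auc],
            "chosen_threshold": float(self.chosen_threshold),
            "chosen_taxa": list(self.chosen_taxa.taxa),
            "cv_scheme": self.cv_scheme,
            "score_spec": self.score_spec,
            "orientation_sign": self.orientation_sign,
            "max_cv_auc": float(np.max(self.cv_auc)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @property
    def cv_scores(self) -> RiskScoreVector:
        return RiskScoreVector(
            list(self.sample_ids),
            self.per_sample_cv_scores,
            f"cv_{self.score_spec}",
            self.score_spec if self.score_spec in ALPHA_INDICES else "weighted_sum",
        )


def candidate_thresholds(da: DAResult, max_grid: int = 100) -> np.ndarray:
    """Grid of candidate cutoffs: sorted unique p-values (quantile-thinned to
    ``max_grid``) plus a terminal value just above 1 so the full table is
    always a candidate.  Each value t defines the set {taxa : p < t}."""
    uniq = np.unique(da.p_value)
    if uniq.size > max_grid:
        qs = np.linspace(0, 1, max_grid)
        # nearest-rank quantiles keep every grid value an observed p-value,
        # so a thinned grid is a subset of the full one
        uniq = np.unique(np.quantile(uniq, qs, method="nearest"))
    return np.append(uniq, 1.0 + TERMINAL_EPS)


def grid_score_matrix(
    values: np.ndarray,
    p_values: np.ndarray,
    thresholds: np.ndarray,
    score_spec: str,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Score every sample at every threshold of a nested P+T path.

    ``values`` is the Q x n matrix the score reads (relative abundances for
    diversity/sum scores, signed-log-count inputs for ``weighted_sum`` with
    explicit weights).  Exploits nestedness: sorting features by p-value turns
    each threshold into a prefix, so prefix sums give all thresholds in O(Qn).
    Returns a (n_thresholds x n) matrix; empty or all-absent sub-communities
    receive the minimal-diversity limit of the index.
    """
    order = np.argsort(p_values, kind="stable")
    sorted_p = p_values[order]
    m = values[order]
    counts = np.searchsorted(sorted_p, thresholds, side="left")
    n = m.shape[1]
    zero_row = np.zeros((1, n))
    s = np.vstack([zero_row, np.cumsum(m, axis=0)])  # prefix sums of abundances
    if score_spec == "shannon":
        t = np.vstack([zero_row, np.cumsum(special.xlogy(m, m), axis=0)])
        S = s[counts]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(S > 0, t[counts] / np.where(S > 0, S, 1.0) - np.log(np.where(S > 0, S, 1.0)), DEGENERATE_SCORE["shannon"])
        return out
    if score_spec == "simpson":
        q2 = np.vstack([zero_row, np.cumsum(m**2, axis=0)])
        S = s[counts]
        return np.where(S > 0, q2[counts] / np.where(S > 0, S, 1.0) ** 2, DEGENERATE_SCORE["simpson"])
    if score_spec == "observed":
        pres = np.vstack([zero_row, np.cumsum(m > 0, axis=0)])
        return -pres[counts]
    if score_spec == "unweighted_sum":
        return s[counts]
    if score_spec == "weighted_sum":
        if weights is None:
            raise ValidationError("weighted_sum requires per-feature weights")
        wm = np.vstack([zero_row, np.cumsum(weights[order][:, None] * m, axis=0)])
        return wm[counts]
    raise ValidationError(f"score spec {score_spec!r} has no fast grid path")


def _resolve_folds(y: np.ndarray, cv: str, k: int, seed: int):
    n = y.size
    if cv == "loo":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
        scheme = "loo"
    elif cv == "kfold":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in skf.split(np.zeros(n), y)]
        scheme = f"kfold(k={k}, seed={seed})"
    else:
        raise ValidationError(f"unknown CV scheme {cv!r}")
    for i, (tr, _) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise SelectionError(f"fold {i} has a single outcome class in training")
    return folds, scheme


def fold_selected_taxa(
    table: FeatureTable,
    outcome,
    train_idx: np.ndarray,
    threshold: float,
    da_method: str = "wilcoxon",
) -> list[str]:
    """Taxa a fold selects at a threshold, from training samples only."""
    y = np.asarray(outcome, dtype=int)
    sub_table = _subset_samples(table, train_idx)
    da = run_da(sub_table, y[train_idx], method=da_method)
    keep = da.p_value < threshold
    return [f for f, k in zip(da.feature_ids, keep) if k]


def _subset_samples(table: FeatureTable, idx: np.ndarray) -> FeatureTable:
    return FeatureTable(
        list(table.feature_ids),
        [table.sample_ids[i] for i in idx],
        table.values[:, idx],
        table.kind,
        taxonomy=table.taxonomy,
        tree=table.tree,
        subset=table.subset,
    )


def pt_select(
    table: FeatureTable,
    outcome,
    da_method: Union[str, DAResult] = "wilcoxon",
    score_spec: str = "shannon",
    cv: str = "loo",
    k: int = 5,
    seed: int = 17,
    max_grid: int = 100,
    da_scope: str = "per_fold",
    orient: str = "fixed",
    tree=None,
) -> PTResult:
    """Choose the p-value cutoff maximizing cross-validated held-out AUC.

    ``da_method`` may be a built-in test name or an imported :class:`DAResult`
    (then used for every fold, which leaks the held-out samples' contribution
    to the external test — warned).  ``da_scope='full'`` reuses the full-data
    built-in DA across folds for comparison with the non-nested variant.
    """
    if score_spec not in SCORE_SPECS:
        raise ValidationError(f"unknown score spec {score_spec!r}")
    if score_spec == "pd":
        raise ValidationError("P+T over the PD index is not supported; select with "
                              "another index and score with 'pd' afterwards")
    y = np.asarray(outcome, dtype=int)
    if y.shape != (table.n_samples,):
        raise ValidationError("outcome length does not match table samples")
    if len(np.unique(y)) < 2 or min(int(y.sum()), int((y == 0).sum())) < 2:
        raise ValidationError("need at least 2 samples per outcome class")

    rel = _as_relative(table)
    imported = isinstance(da_method, DAResult)
    if imported:
        da_full = da_method
        if da_full.feature_ids != table.feature_ids:
            raise ValidationError("imported DA features do not match the table")
        warnings.warn(
            "imported DA results are reused across folds; held-out samples "
            "contributed to the external test (selection leakage caveat)"
        )
        method_label = da_full.method
    else:
        da_full = run_da(table, y, method=da_method)
        method_label = da_method
    thresholds = candidate_thresholds(da_full, max_grid)

    folds, scheme = _resolve_folds(y, cv, k, seed)
    n = table.n_samples
    scores = np.zeros((thresholds.size, n))
    fold_p = np.zeros((len(folds), table.n_features))
    for fi, (tr, te) in enumerate(folds):
        if imported or da_scope == "full":
            p_tr, eff_tr = da_full.p_value, da_full.effect
        else:
            da_tr = run_da(_subset_samples(table, tr), y[tr], method=da_method)
            p_tr, eff_tr = da_tr.p_value, da_tr.effect
        fold_p[fi] = p_tr
        w = eff_tr if score_spec == "weighted_sum" else None
        scores[:, te] = grid_score_matrix(rel.values[:, te], p_tr, thresholds, score_spec, weights=w)

    cv_auc = np.array([mann_whitney_auc(scores[t], y) for t in range(thresholds.size)])
    sign = 1
    if orient == "auto":
        flipped = np.maximum(cv_auc, 1 - cv_auc)
        sign_per = np.where(cv_auc >= 0.5, 1, -1)
        cv_auc_eff = flipped
    else:
        sign_per = np.ones(thresholds.size, dtype=int)
        cv_auc_eff = cv_auc

    full_counts = np.searchsorted(np.sort(da_full.p_value), thresholds, side="left")
    nonempty = full_counts > 0
    if not nonempty.any():
        raise SelectionError("all thresholds yield empty sub-communities")
    best_auc = cv_auc_eff[nonempty].max()
    # tie-break: smallest threshold (fewest taxa) among the maximizers
    candidates = np.where(nonempty & np.isclose(cv_auc_eff, best_auc, atol=1e-12, rtol=0))[0]
    chosen_idx = int(candidates[0])
    chosen_threshold = float(thresholds[chosen_idx])
    sign = int(sign_per[chosen_idx])

    keep = da_full.p_value < chosen_threshold
    order = np.argsort(da_full.p_value[keep], kind="stable")
    taxa = [f for f, kp in zip(da_full.feature_ids, keep) if kp]
    effects = da_full.effect[keep]
    taxa = [taxa[i] for i in order]
    effects = effects[order]
    chosen = SubCommunity(taxa, chosen_threshold, method_label, weights=effects)

    selection_proportion = (fold_p < chosen_threshold).mean(axis=0)
    return PTResult(
        thresholds=thresholds,
        cv_auc=cv_auc if orient == "fixed" else cv_auc_eff,
        chosen_threshold=chosen_threshold,
        chosen_taxa=chosen,
        cv_scheme=scheme,
        score_spec=score_spec,
        per_sample_cv_scores=sign * scores[chosen_idx],
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        selection_proportion=selection_proportion,
        da_full=da_full,
        orientation_sign=sign,
    )


def apply_subcommunity(
    validation_table: FeatureTable,
    sub: SubCommunity,
    score_spec: str = "shannon",
    tree=None,
) -> RiskScoreVector:
    """Score a new cohort with a previously selected sub-community.

    No re-selection and no re-weighting: discovery taxa absent from the
    validation table are zero-filled (warned); it is an error if *every*
    discovery taxon is absent.
    """
    present = set(validation_table.feature_ids)
    if not any(t in present for t in sub.taxa):
        raise ValidationError("no sub-community taxon is present in the validation table")
    rel = _as_relative(validation_table)
    if score_spec in ALPHA_INDICES:
        return mrs_alpha(rel, sub, index=score_spec, tree=tree)
    if score_spec == "unweighted_sum":
        return mrs_standard(rel, sub, scheme="unweighted")
    if score_spec == "weighted_sum":
        return mrs_standard(rel, sub, scheme="weighted")
    raise ValidationError(f"unknown score spec {score_spec!r}")
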