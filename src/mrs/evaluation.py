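"""ROC/AUC machinery, DeLong confidence intervals, and risk classification.

AUC is the Mann–Whitney estimator (ties counted one half): the probability
that a randomly drawn case outscores a randomly drawn control.  The default
95% CI uses DeLong's structural-components variance; a stratified bootstrap
is available as an alternative and as the fallback when the DeLong variance
degenerates (AUC exactly 0 or 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._exceptions import ValidationError
from .mrs_core import RiskScoreVector


@dataclass
class ROCSummary:
    auc: float
    n_cases: int
    n_controls: int
    curve: np.ndarray  # (k, 2) of (fpr, tpr), (0,0) .. (1,1)
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "auc": float(self.auc),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        if self.ci_method is not None:
            d.update(
                ci_low=float(self.ci_low),
                ci_high=float(self.ci_high),
                ci_method=self.ci_method,
            )
        return d


@dataclass
class ClassificationReport:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    n_included: int
    n_excluded: int
    confusion: tuple  # (TP, FP, TN, FN)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "confusion": {k: int(v) for k, v in zip("TP FP TN FN".split(), self.confusion)},
        }


def _as_arrays(scores, labels):
    x = scores.score if isinstance(scores, RiskScoreVector) else np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape != y.shape:
        raise ValidationError("scores and labels have different lengths")
    if not np.all(np.isin(y, [0, 1])):
        raise ValidationError("labels must be binary 0/1")
    return x, y


def mann_whitney_auc(scores, labels) -> float:
    """AUC via midranks: (sum of case ranks - n1(n1+1)/2) / (n1 n0)."""
    x, y = _as_arrays(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("both outcome classes are required for AUC")
    ranks = stats.rankdata(x)
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def roc_auc(scores, labels) -> ROCSummary:
    """ROC curve (threshold sweep) and Mann–Whitney AUC."""
    x, y = _as_arrays(scores, labels)
    auc = mann_whitney_auc(x, y)
    fpr, tpr, _ = _sk_roc_curve(y, x)
    curve = np.column_stack([fpr, tpr])
    return ROCSummary(auc, int(y.sum()), int((y == 0).sum()), curve)


def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """Structural components: V10_i = mean_j psi(x_i, y_j), V01_j = mean_i psi."""
    psi = (cases[:, None] > controls[None, :]).astype(float)
    psi += 0.5 * (cases[:, None] == controls[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(scores, labels) -> float:
    x, y = _as_arrays(scores, labels)
    cases, controls = x[y == 1], x[y == 0]
    v10, v01 = _delong_components(cases, controls)
    return v10.var(ddof=1) / cases.size + v01.var(ddof=1) / controls.size


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 17,
    alpha: float = 0.05,
    scale: str = "logit",
) -> ROCSummary:
    """AUC with a 95% (by default) confidence interval.

    The DeLong interval is constructed on the logit scale by default (delta
    method on logit(AUC)) and back-transformed: at AUCs near 1 the plain
    normal-scale interval is anti-conservative, while the logit interval
    stays inside (0, 1) and widens asymmetrically toward 0.5.
    ``scale='linear'`` gives the plain interval truncated to [0, 1].
    """
    x, y = _as_arrays(scores, labels)
    if int(y.sum()) < 2 or int((y == 0).sum()) < 2:
        raise ValidationError("need at least 2 samples per class for a CI")
    summary = roc_auc(x, y)
    if method == "delong":
        var = delong_variance(x, y)
        if var == 0 or summary.auc in (0.0, 1.0):
            warnings.warn("degenerate DeLong variance; falling back to bootstrap CI")
            return auc_ci(x, y, method="bootstrap", n_boot=n_boot, seed=seed, alpha=alpha)
        z = stats.norm.ppf(1 - alpha / 2)
        a = summary.auc
        if scale == "logit":
            se_logit = np.sqrt(var) / (a * (1 - a))
            lo = special.expit(special.logit(a) - z * se_logit)
            hi = special.expit(special.logit(a) + z * se_logit)
        elif scale == "linear":
            half = z * np.sqrt(var)
            lo, hi = max(0.0, a - half), min(1.0, a + half)
        else:
            raise ValidationError(f"unknown CI scale {scale!r}")
        summary.ci_low = float(lo)
        summary.ci_high = float(hi)
        summary.ci_method = "delong"
        return summary
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cases, controls = x[y == 1], x[y == 0]
        aucs = np.empty(n_boot)
        yy = np.concatenate([np.ones(cases.size, int), np.zeros(controls.size, int)])
        for b in range(n_boot):
            xb = np.concatenate(
                [rng.choice(cases, cases.size), rng.choice(controls, controls.size)]
            )
            aucs[b] = mann_whitney_auc(xb, yy)
        summary.ci_low = float(np.percentile(aucs, 100 * alpha / 2))
        summary.ci_high = float(np.percentile(aucs, 100 * (1 - alpha / 2)))
        summary.ci_method = "bootstrap"
        return summary
    raise ValidationError(f"unknown CI method {method!r}")


def risk_stratify(scores, rule: str = "mean"):
    """Dichotomize a risk score: high iff score > mean (or > third quartile).

    Returns ``(labels, counts)`` with labels 1 = high risk and
    ``counts = (n_high, n_low)``; a score exactly at the cut is low risk.
    """
    x = scores.score if isinstance(scores, RiskScoreVector) else np.asarray(scores, dtype=float)
    if rule == "mean":
        cut = x.mean()
    elif rule == "quartile3":
        cut = np.quantile(x, 0.75)  # linear-interpolation quantile
    else:
        raise ValidationError(f"unknown stratification rule {rule!r}")
    high = (x > cut).astype(int)
    return high, (int(high.sum()), int((high == 0).sum()))


def report_from_confusion(tp: int, fp: int, tn: int, fn: int, n_excluded: int = 0) -> ClassificationReport:
    n = tp + fp + tn + fn
    if n == 0:
        raise ValidationError("empty confusion table")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    return ClassificationReport(sens, spec, acc, f1, n, n_excluded, (tp, fp, tn, fn))


def extreme_category_classification(
    score_list: list,
    labels,
    rule: str = "mean",
) -> ClassificationReport:
    """Classify using only subjects with concordant risk categories.

    Each score is dichotomized at its own mean; subjects labeled high risk by
    *all* scores are predicted cases, low risk by all scores predicted
    controls, and discordant subjects are excluded from the metrics.
    """
    if len(score_list) < 2:
        raise ValidationError("need at least 2 risk scores")
    y = np.asarray(labels, dtype=int)
    highs = []
    ids = None
    for s in score_list:
        if isinstance(s, RiskScoreVector):
            if ids is not None and s.sample_ids != ids:
                raise ValidationError("risk scores cover different samples")
            ids = s.sample_ids
        h, _ = risk_stratify(s, rule=rule)
        highs.append(h.astype(bool))
    highs = np.array(highs)
    all_high = highs.all(axis=0)
    all_low = (~highs).all(axis=0)
    included = all_high | all_low
    if not included.any():
        raise ValidationError("no subjects with concordant risk categories")
    pred = all_high[included].astype(int)
    truth = y[included]
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    return report_from_confusion(tp, fp, tn, fn, n_excluded=int((~included).sum()))
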