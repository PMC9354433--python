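"""Differential-abundance testing against a binary outcome.

Two built-in tests — a Wilcoxon rank-sum on relative abundances and a Welch
t-test on centered log-ratio (CLR) transformed counts — plus an import path
for results produced externally by dedicated DA tools (ANCOM-BC, ALDEx2,
Maaslin2, DESeq2, ...).  Every route yields a :class:`DAResult`: per-feature
p-value plus a signed effect with the convention *positive = enriched in
cases*.  P-values are left unadjusted because the downstream threshold search
operates on raw p-values; a Benjamini–Hochberg column is attached for
reporting only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ValidationError
from .feature_io import COUNTS, RELATIVE_ABUNDANCE, FeatureTable

DEFAULT_EXACT_THRESHOLD = 10
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DAResult:
    """Per-feature association evidence: p-value and signed effect size."""

    feature_ids: list[str]
    p_value: np.ndarray
    effect: np.ndarray
    method: str
    n_cases: int
    n_controls: int
    degenerate: np.ndarray = field(default=None)
    p_adjusted: Optional[np.ndarray] = None  # BH, reporting only

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        q = len(self.feature_ids)
        if len(set(self.feature_ids)) != q:
            raise ValidationError("duplicate feature identifiers in DA result")
        if self.p_value.shape != (q,) or self.effect.shape != (q,):
            raise ValidationError("p_value/effect length mismatch")
        if np.any((self.p_value < 0) | (self.p_value > 1)) or np.any(~np.isfinite(self.p_value)):
            raise ValidationError("p-values must lie in [0, 1]")
        if np.any(~np.isfinite(self.effect)):
            raise ValidationError("effects must be finite")
        if self.degenerate is None:
            self.degenerate = np.zeros(q, dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.p_adjusted is None:
            self.p_adjusted = stats.false_discovery_control(self.p_value)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "p_value": self.p_value,
                "effect": self.effect,
                "p_adjusted": self.p_adjusted,
                "degenerate": self.degenerate,
                "method": self.method,
            }
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _check_outcome(outcome: np.ndarray, n_samples: int) -> np.ndarray:
    y = np.asarray(outcome, dtype=int)
    if y.shape != (n_samples,):
        raise ValidationError("outcome length does not match number of samples")
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError("need at least 2 samples per outcome class")
    return y


def _exact_ranksum_p(values: np.ndarray, case_mask: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating case-index combinations.

    p = P(|W - E[W]| >= |w_obs - E[W]|) over all equally likely assignments of
    the case labels; average ranks make this valid under ties.
    """
    n = values.size
    n1 = int(case_mask.sum())
    ranks = stats.rankdata(values)
    w_obs = ranks[case_mask].sum()
    mean_w = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - mean_w)
    total = 0
    hits = 0
    for combo in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mean_w) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_da(
    table: FeatureTable,
    outcome,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> DAResult:
    """Per-taxon two-sided Wilcoxon rank-sum test on relative abundances.

    Exact by enumeration for total n <= ``exact_threshold``; otherwise a
    normal approximation with tie and continuity corrections.  The effect is
    the difference in mean relative abundance (cases - controls).
    """
    if table.kind != RELATIVE_ABUNDANCE:
        raise ValidationError("wilcoxon_da expects a relative-abundance table")
    y = _check_outcome(outcome, table.n_samples)
    case = y == 1
    n = table.n_samples
    n1 = int(case.sum())
    n0 = n - n1
    values = table.values
    effect = values[:, case].mean(axis=1) - values[:, ~case].mean(axis=1)
    constant = np.ptp(values, axis=1) == 0

    p = np.ones(table.n_features)
    if n <= exact_threshold:
        for j in range(table.n_features):
            if constant[j]:
                continue
            p[j] = _exact_ranksum_p(values[j], case)
    else:
        ranks = stats.rankdata(values, axis=1)
        r1 = ranks[:, case].sum(axis=1)
        u1 = r1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n0 / 2.0
        tie_term = np.zeros(table.n_features)
        for j in range(table.n_features):
            _, cnt = np.unique(values[j], return_counts=True)
            tie_term[j] = np.sum(cnt**3 - cnt)
        var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(u1 - mu) - 0.5) / np.sqrt(var)
        z = np.clip(np.where(var > 0, z, 0.0), 0.0, None)
        p = np.minimum(2 * stats.norm.sf(z), 1.0)
        p[var == 0] = 1.0
    p[constant] = 1.0
    effect[constant] = 0.0
    return DAResult(
        list(table.feature_ids), p, effect, "wilcoxon", n1, n0, degenerate=constant
    )


def clr_transform(table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Centered log-ratio transform of a counts table (per-sample columns sum to 0)."""
    if table.kind != COUNTS:
        raise ValidationError("clr_transform expects a counts table")
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be > 0")
    logx = np.log(table.values + pseudocount)
    return logx - logx.mean(axis=0, keepdims=True)


def clr_ttest_da(
    table: FeatureTable,
    outcome,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DAResult:
    """Welch two-sample t-test per taxon on CLR-transformed counts."""
    y = _check_outcome(outcome, table.n_samples)
    clr = clr_transform(table, pseudocount)
    case = y == 1
    a, b = clr[:, case], clr[:, ~case]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    effect = a.mean(axis=1) - b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    both_const = (var_a == 0) & (var_b == 0)
    degenerate = both_const.copy()
    # zero within-group variance in both groups: equal means -> p=1, else p->0
    p[both_const & (np.abs(effect) <= 1e-12)] = 1.0
    p[both_const & (np.abs(effect) > 1e-12)] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    return DAResult(
        list(table.feature_ids), p, effect, "clr_ttest", int(case.sum()),
        int((~case).sum()), degenerate=degenerate,
    )


def import_da_results(path) -> DAResult:
    """Read an external DA result TSV with columns feature_id, p_value, effect."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "p_value", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"DA import is missing required columns: {sorted(missing)}")
    p = df["p_value"].to_numpy(dtype=float)
    n_missing = int(np.isnan(p).sum())
    if n_missing:
        warnings.warn(f"{n_missing} features with missing p-value set to 1")
        p = np.nan_to_num(p, nan=1.0)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("imported p-values outside [0, 1]")
    effect = df["effect"].to_numpy(dtype=float)
    if np.any(~np.isfinite(effect)):
        raise ValidationError("imported effects must be finite")
    method = str(df["method"].iloc[0]) if "method" in df.columns and len(df) else "imported"
    return DAResult(list(df["feature_id"].astype(str)), p, effect, method, 0, 0)


def run_da(table: FeatureTable, outcome, method: str = "wilcoxon", **kwargs) -> DAResult:
    """Dispatch to a built-in DA test by name."""
    if method == "wilcoxon":
        rel = table
        if table.kind == COUNTS:
            from .feature_io import to_relative_abundance

            rel = to_relative_abundance(table)
        return wilcoxon_da(rel, outcome, **kwargs)
    if method == "clr_ttest":
        return clr_ttest_da(table, outcome, **kwargs)
    raise ValidationError(f"unknown DA method {method!r}")
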