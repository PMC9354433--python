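"""Per-sample risk scores from a selected microbial sub-community.

The community-based score MRS_alpha is the alpha diversity of the selected
sub-community, computed on abundances renormalized within that sub-community
and oriented so that *lower sub-community diversity means a higher score*
(the Shannon variant is literally sum M~ ln M~, i.e. the Shannon index
without the negative sign).  The summation-based score MRS_S is the
(weighted) sum of the original relative abundances of the selected taxa.  A
signed log-count score covers transcriptome-type companion data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from ._exceptions import ValidationError
from .feature_io import COUNTS, FeatureTable, align_to_taxa, to_relative_abundance

ALPHA_INDICES = ("shannon", "simpson", "observed", "pd")
SUM_SCHEMES = ("unweighted", "weighted")

#: Score value assigned to samples whose selected taxa are all absent:
#: the minimal-diversity limit of each index.
DEGENERATE_SCORE = {"shannon": 0.0, "simpson": 1.0, "observed": 0.0, "pd": 0.0}

ORIENTATION_NOTE = (
    "lower sub-community diversity => higher score "
    "(cases are expected to score higher than controls)"
)


@dataclass
class SubCommunity:
    """An ordered set of selected taxa with the p-value cutoff that produced it."""

    taxa: list[str]
    threshold: float = float("nan")
    source: str = ""
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        if not self.taxa:
            raise ValidationError("sub-community is empty")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxa in sub-community")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.taxa),):
                raise ValidationError("weights do not align 1:1 with taxa")

    @property
    def size(self) -> int:
        return len(self.taxa)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature_id": self.taxa})
        if self.weights is not None:
            df["effect"] = self.weights
        df["threshold"] = self.threshold
        df["source"] = self.source
        return df

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SubCommunity":
        df = pd.read_csv(path, sep="\t")
        if "feature_id" not in df.columns:
            raise ValidationError("sub-community file needs a feature_id column")
        weights = df["effect"].to_numpy(float) if "effect" in df.columns else None
        threshold = float(df["threshold"].iloc[0]) if "threshold" in df.columns else float("nan")
        source = str(df["source"].iloc[0]) if "source" in df.columns else ""
        return cls(list(df["feature_id"].astype(str)), threshold, source, weights)


@dataclass
class RiskScoreVector:
    """One named, oriented risk score per sample."""

    sample_ids: list[str]
    score: np.ndarray
    name: str
    index: str
    orientation_note: str = ORIENTATION_NOTE
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValidationError("score length does not match sample_ids")
        if np.any(~np.isfinite(self.score)):
            raise ValidationError("non-finite risk scores")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.sample_ids), dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "score": self.score,
                "name": self.name,
                "degenerate_flag": self.degenerate,
            }
        )

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _as_relative(table: FeatureTable) -> FeatureTable:
    if table.kind == COUNTS:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return to_relative_abundance(table)
    return table


def renormalize_subcommunity(table: FeatureTable, sub: SubCommunity):
    """Renormalize abundances within the sub-community: M~_ij = M_ij / sum_j M_ij.

    Returns ``(M_tilde, degenerate)`` where ``M_tilde`` is p x n and
    ``degenerate`` flags samples whose selected taxa are all zero (their
    columns stay all-zero).
    """
    rel = _as_relative(table)
    aligned = align_to_taxa(rel, sub.taxa)
    m = aligned.values
    sums = m.sum(axis=0)
    degenerate = sums == 0
    mt = m / np.where(degenerate, 1.0, sums)
    return mt, degenerate


def _faith_pd_lengths(tree, present_sets: list[set], include_root_path: bool) -> np.ndarray:
    """Total branch length of the minimal subtree spanning each present leaf set."""
    tips = {t.name: t for t in tree.tips()}
    paths = {}  # leaf name -> list of nodes from leaf up to (excluding) root
    for name, tip in tips.items():
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[name] = path
    out = np.zeros(len(present_sets))
    for i, leaves in enumerate(present_sets):
        if not leaves:
            continue
        node_union: dict = {}
        common = None
        for name in leaves:
            p = paths[name]
            for nd in p:
                node_union[id(nd)] = nd
            s = {id(nd) for nd in p}
            common = s if common is None else (common & s)
        total = sum((nd.length or 0.0) for nd in node_union.values())
        if not include_root_path and common:
            # subtract branches above (and including the branch of) the LCA
            any_path = paths[next(iter(leaves))]
            for nd in any_path:
                if id(nd) in common:
                    total -= nd.length or 0.0
        out[i] = total
    return out


def mrs_alpha(
    table: FeatureTable,
    sub: SubCommunity,
    index: str = "shannon",
    tree=None,
    include_root_path: bool = False,
    name: Optional[str] = None,
) -> RiskScoreVector:
    """Sub-community alpha-diversity risk score (MRS_alpha).

    shannon: sum M~ ln M~ (0 ln 0 = 0), range [-ln p, 0]; simpson: sum M~^2
    (concentration); observed: -(number of present selected taxa); pd:
    -(branch length spanning the present selected taxa).  Every variant is
    oriented so lower diversity => higher score; samples with no selected
    taxon present receive the minimal-diversity limit and a degenerate flag.
    """
    if index not in ALPHA_INDICES:
        raise ValidationError(f"unknown alpha index {index!r}")
    mt, degenerate = renormalize_subcommunity(table, sub)
    if index == "shannon":
        score = special.xlogy(mt, mt).sum(axis=0)
    elif index == "simpson":
        score = (mt**2).sum(axis=0)
        score[degenerate] = DEGENERATE_SCORE["simpson"]
    elif index == "observed":
        score = -(mt > 0).sum(axis=0).astype(float)
    else:  # pd
        tree = tree if tree is not None else table.tree
        if tree is None:
            raise ValidationError("index 'pd' requires a phylogenetic tree")
        leaf_names = {t.name for t in tree.tips()}
        missing = [t for t in sub.taxa if t not in leaf_names]
        if missing:
            raise ValidationError(f"sub-community taxa absent from tree leaves: {missing}")
        present_sets = [
            {sub.taxa[j] for j in np.where(mt[:, i] > 0)[0]} for i in range(mt.shape[1])
        ]
        score = -_faith_pd_lengths(tree, present_sets, include_root_path)
    return RiskScoreVector(
        list(table.sample_ids),
        score,
        name or f"MRS_alpha_{index}",
        index,
        degenerate=degenerate,
    )


def mrs_standard(
    table: FeatureTable,
    sub: SubCommunity,
    scheme: str = "unweighted",
    name: Optional[str] = None,
) -> RiskScoreVector:
    """Summation-based risk score MRS_S = sum_j w_j M_ij over the selected taxa.

    Uses the *original* relative abundances (no sub-community renormalization);
    unweighted sets all weights to 1, weighted uses the stored effect sizes.
    """
    if scheme not in SUM_SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    rel = _as_relative(table)
    aligned = align_to_taxa(rel, sub.taxa)
    if scheme == "weighted":
        if sub.weights is None:
            raise ValidationError("weighted scheme requires sub-community weights")
        w = sub.weights
    else:
        w = np.ones(sub.size)
    score = w @ aligned.values
    degenerate = aligned.values.sum(axis=0) == 0
    return RiskScoreVector(
        list(table.sample_ids),
        score,
        name or f"MRS_{'w' if scheme == 'weighted' else 'unw'}S",
        f"{scheme}_sum",
        orientation_note="weighted sum of selected relative abundances",
        degenerate=degenerate,
    )


def signed_logcount_score(
    table: FeatureTable,
    features: list[str],
    signs,
    name: str = "Host",
) -> RiskScoreVector:
    """Signed sum of log-transformed counts: score_i = sum_j sign_j ln(count_ij + 1)."""
    if table.kind != COUNTS:
        raise ValidationError("signed_logcount_score expects a counts table")
    features = [str(f) for f in features]
    signs = np.asarray(signs, dtype=float)
    if signs.shape != (len(features),) or not np.all(np.isin(signs, [-1.0, 1.0])):
        raise ValidationError("signs must be +1/-1 and align with features")
    pos = {f: i for i, f in enumerate(table.feature_ids)}
    missing = [f for f in features if f not in pos]
    if missing:
        raise ValidationError(f"features absent from table: {missing}")
    idx = [pos[f] for f in features]
    score = signs @ np.log1p(table.values[idx])
    return RiskScoreVector(
        list(table.sample_ids),
        score,
        name,
        "signed_logcount",
        orientation_note="signed sum of ln(count+1); positive sign = enriched in cases",
    )


def standardize_scores(scores: RiskScoreVector) -> RiskScoreVector:
    """Z-standardize a score vector (mean 0, sample sd 1)."""
    x = scores.score
    if x.size < 2:
        raise ValidationError("need at least 2 samples to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant score vector")
    return RiskScoreVector(
        list(scores.sample_ids),
        (x - x.mean()) / sd,
        scores.name,
        scores.index,
        orientation_note=scores.orientation_note,
        degenerate=scores.degenerate.copy(),
    )
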