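"""Feature tables, sample metadata, and phylogenetic trees.

A :class:`FeatureTable` holds a taxon-by-sample matrix of counts or relative
abundances (features in rows, samples in columns) together with identifier
lists and optional taxonomy / tree annotations.  All downstream stages of the
risk-score pipeline consume this container, so validation is strict: unique
identifiers, non-negative values, and — for relative abundances — per-sample
columns that sum to one (all-zero columns are tolerated and flagged rather
than dropped, so sample alignment with metadata is never silently broken).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import skbio

from ._exceptions import ValidationError

COUNTS = "counts"
RELATIVE_ABUNDANCE = "relative_abundance"

_REL_TOL = 1e-9


@dataclass
class FeatureTable:
    """Taxon-by-sample abundance matrix (Q features x n samples)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str
    taxonomy: Optional[dict[str, str]] = None
    tree: Optional[skbio.TreeNode] = None
    provenance: dict = field(default_factory=dict)
    #: True for tables restricted to a feature subset, whose relative-abundance
    #: columns legitimately no longer sum to 1.
    subset: bool = False

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix (features x samples)")
        q, n = self.values.shape
        if q != len(self.feature_ids) or n != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != q:
            raise ValidationError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in feature table")
        if np.any(self.values < 0):
            raise ValidationError("negative values in feature table")
        if self.kind not in (COUNTS, RELATIVE_ABUNDANCE):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        if self.kind == RELATIVE_ABUNDANCE and not self.subset:
            sums = self.values.sum(axis=0)
            bad = ~(np.isclose(sums, 1.0, atol=_REL_TOL, rtol=0) | (sums == 0))
            if np.any(bad):
                offenders = [self.sample_ids[i] for i in np.where(bad)[0][:5]]
                raise ValidationError(
                    f"relative-abundance columns must sum to 1 (or be all-zero); "
                    f"offending samples: {offenders}"
                )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def write(self, path, format: str = "tsv") -> None:
        sep = "\t" if format == "tsv" else ","
        self.to_dataframe().to_csv(path, sep=sep, index_label="feature_id")

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids),
            list(self.sample_ids),
            self.values.copy(),
            self.kind,
            taxonomy=dict(self.taxonomy) if self.taxonomy else None,
            tree=self.tree,
            provenance=dict(self.provenance),
            subset=self.subset,
        )


@dataclass
class SampleMetadata:
    """Per-sample binary outcome (1 = case/diseased/deceased) plus optional covariates."""

    sample_ids: list[str]
    outcome: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.outcome = np.asarray(self.outcome, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers in metadata")
        if self.outcome.shape != (len(self.sample_ids),):
            raise ValidationError("outcome length does not match sample_ids")
        if not np.all(np.isin(self.outcome, [0, 1])):
            raise ValidationError("outcome must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int((self.outcome == 0).sum())


def load_feature_table(
    path,
    format: str = "tsv",
    orientation: str = "features_in_rows",
    kind: Optional[str] = None,
) -> FeatureTable:
    """Read a delimited feature table and infer whether it holds counts.

    Inference: all-integer body -> counts; otherwise columns summing to ~1 ->
    relative abundance; anything else is ambiguous and requires an explicit
    ``kind``.
    """
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "features_in_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric table body: {exc}") from exc
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValidationError("duplicate feature or sample identifiers")
    if np.any(values < 0):
        raise ValidationError("negative values in feature table")
    if kind is None:
        if np.allclose(values, np.round(values), atol=0, rtol=0):
            kind = COUNTS
        elif np.all(
            np.isclose(values.sum(axis=0), 1.0, atol=1e-6, rtol=0)
            | (values.sum(axis=0) == 0)
        ):
            kind = RELATIVE_ABUNDANCE
        else:
            raise ValidationError(
                "cannot infer table kind (neither integer counts nor columns "
                "summing to 1); pass kind='counts' or kind='relative_abundance'"
            )
    return FeatureTable(list(df.index), list(df.columns), values, kind)


def load_metadata(path, case_label: Optional[str] = None, format: str = "tsv") -> SampleMetadata:
    """Read a metadata table with ``sample_id`` and ``outcome`` columns."""
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    for col in ("sample_id", "outcome"):
        if col not in df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    raw = df["outcome"]
    if case_label is not None:
        outcome = (raw.astype(str) == str(case_label)).astype(int).to_numpy()
    else:
        try:
            outcome = raw.astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                "outcome is not 0/1 coded; pass case_label to map a string level"
            ) from exc
    covars = df.drop(columns=["sample_id", "outcome"])
    return SampleMetadata(
        list(df["sample_id"].astype(str)),
        outcome,
        covariates=covars if covars.shape[1] else None,
    )


def load_tree(path) -> skbio.TreeNode:
    """Read a rooted Newick tree; branch lengths must be non-negative."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValidationError("negative branch length in tree")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def align_samples(table: FeatureTable, metadata: SampleMetadata) -> SampleMetadata:
    """Reorder metadata rows to the table's sample order; error on mismatch."""
    pos = {s: i for i, s in enumerate(metadata.sample_ids)}
    missing = [s for s in table.sample_ids if s not in pos]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    idx = [pos[s] for s in table.sample_ids]
    covars = metadata.covariates.iloc[idx].reset_index(drop=True) if metadata.covariates is not None else None
    return SampleMetadata(list(table.sample_ids), metadata.outcome[idx], covariates=covars)


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its sum; all-zero columns stay zero (warned)."""
    if table.kind == RELATIVE_ABUNDANCE:
        warnings.warn("table is already relative abundance; no-op")
        return table.copy()
    sums = table.values.sum(axis=0)
    zero_cols = np.where(sums == 0)[0]
    safe = np.where(sums == 0, 1.0, sums)
    values = table.values / safe
    out = table.copy()
    out.values = values
    out.kind = RELATIVE_ABUNDANCE
    if zero_cols.size:
        zero_ids = [table.sample_ids[i] for i in zero_cols]
        warnings.warn(f"all-zero sample columns left as zero: {zero_ids}")
        out.provenance["all_zero_samples"] = zero_ids
    return out


def filter_features(
    table: FeatureTable,
    min_prevalence: float = 0.1,
    min_mean_abundance: float = 0.0,
) -> FeatureTable:
    """Keep features present in >= ``min_prevalence`` of samples with mean
    relative abundance >= ``min_mean_abundance``."""
    if not 0 <= min_prevalence <= 1:
        raise ValidationError("min_prevalence must lie in [0, 1]")
    prevalence = (table.values > 0).mean(axis=1)
    if table.kind == COUNTS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rel = to_relative_abundance(table).values
    else:
        rel = table.values
    mean_abund = rel.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_abund >= min_mean_abundance)
    if not keep.any():
        raise ValidationError("filter removed every feature")
    out = table.copy()
    out.feature_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    out.values = table.values[keep]
    out.provenance["filter"] = {
        "min_prevalence": min_prevalence,
        "min_mean_abundance": min_mean_abundance,
        "kept": out.feature_ids,
        "dropped": [f for f, k in zip(table.feature_ids, keep) if not k],
    }
    if out.taxonomy:
        out.taxonomy = {f: out.taxonomy[f] for f in out.feature_ids if f in out.taxonomy}
    return out


def align_to_taxa(table: FeatureTable, taxa: list[str]) -> FeatureTable:
    """Restrict/reorder the table to exactly ``taxa``; absent taxa zero-filled.

    Relative abundances are deliberately *not* renormalized here — sub-community
    renormalization is a separate, explicit step.
    """
    taxa = [str(t) for t in taxa]
    if not taxa:
        raise ValidationError("taxa list is empty")
    pos = {f: i for i, f in enumerate(table.feature_ids)}
    values = np.zeros((len(taxa), table.n_samples))
    missing = []
    for row, t in enumerate(taxa):
        if t in pos:
            values[row] = table.values[pos[t]]
        else:
            missing.append(t)
    if missing:
        warnings.warn(f"taxa absent from table zero-filled: {missing}")
    out = FeatureTable(
        taxa,
        list(table.sample_ids),
        values,
        table.kind,
        taxonomy=table.taxonomy,
        tree=table.tree,
        provenance=dict(table.provenance),
        subset=True,
    )
    out.provenance["aligned_missing"] = missing
    return out
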