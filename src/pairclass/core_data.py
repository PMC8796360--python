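"""Expression-matrix data model, I/O, ranking, cohort combination and splitting.

The single input currency of the package is the :class:`ExpressionMatrix`:
genes in rows, samples in columns, values on a raw per-sample scale such as
log2(TPM + 1) or log2 array signal intensities.  No between-sample
normalisation is assumed or performed anywhere — the predictors in this
package are single-sample predictors and must work on each column in
isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class ValidationError(ValueError):
    """Raised when an input matrix or annotation table violates its contract."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with optional per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  All entries must be finite numbers.
    platform, dataset
        Optional per-sample categorical labels (aligned to ``values.columns``).
    """

    values: pd.DataFrame
    platform: pd.Series | None = None
    dataset: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        for name in ("platform", "dataset"):
            meta = getattr(self, name)
            if meta is not None:
                meta = pd.Series(meta)
                if not meta.index.equals(self.values.columns):
                    meta = meta.reindex(self.values.columns)
                    if meta.isna().any():
                        raise ValidationError(f"{name} labels do not cover all samples")
                setattr(self, name, meta)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionMatrix":
        cols = pd.Index(sample_ids)
        return ExpressionMatrix(
            self.values.loc[:, cols],
            None if self.platform is None else self.platform.loc[cols],
            None if self.dataset is None else self.dataset.loc[cols],
        )

    def subset_genes(self, gene_ids: Sequence) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[pd.Index(gene_ids)], self.platform, self.dataset)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            None if self.platform is None else self.platform.copy(),
            None if self.dataset is None else self.dataset.copy(),
        )


class RankedMatrix(ExpressionMatrix):
    """Within-sample (column-wise) ranks of an :class:`ExpressionMatrix`.

    Each column is a permutation of ``1..G`` up to average-rank ties, and is
    therefore invariant under any strictly increasing per-sample transform of
    the source values.
    """


@dataclass
class LabeledCohort:
    """An :class:`ExpressionMatrix` with one class label per sample."""

    expression: ExpressionMatrix
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        cols = self.expression.values.columns
        if not self.labels.index.equals(cols):
            self.labels = self.labels.reindex(cols)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()[:5]
            raise ValidationError(f"samples without a class label: {missing}")

    @property
    def classes(self) -> list:
        return sorted(self.labels.unique().tolist())

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def subset(self, sample_ids: Sequence) -> "LabeledCohort":
        return LabeledCohort(self.expression.subset_samples(sample_ids), self.labels.loc[pd.Index(sample_ids)])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(path, *, sep: str = "\t", duplicate_genes: str = "error") -> ExpressionMatrix:
    """Read a genes × samples expression table (first column = gene id).

    ``duplicate_genes`` controls what happens when a gene identifier occurs on
    more than one row: ``"error"`` (default) rejects the file, ``"median"``
    median-merges the duplicated rows (the common convention when collapsing
    array probes to gene symbols).
    """
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed expression file {path}: {exc}") from exc
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(f"non-numeric expression column(s): {non_numeric}")
    if df.index.has_duplicates:
        if duplicate_genes == "median":
            df = df.groupby(level=0, sort=False).median()
        elif duplicate_genes == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate gene rows (merge disabled): {dups}")
        else:
            raise ValueError(f"unknown duplicate_genes option: {duplicate_genes!r}")
    return ExpressionMatrix(df)


def write_expression(x: ExpressionMatrix, path, *, sep: str = "\t") -> None:
    """Write a matrix readable by :func:`read_expression` (full precision)."""
    x.values.to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_annotations(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a sample annotation table with columns sample_id, class[, platform, dataset]."""
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns or "class" not in df.columns:
        raise ValidationError("annotation table must have 'sample_id' and 'class' columns")
    _check_unique(pd.Index(df["sample_id"]), "sample ids")
    return df.set_index("sample_id")


def cohort_from_frames(expr: ExpressionMatrix, annot: pd.DataFrame) -> LabeledCohort:
    """Assemble a labeled cohort from an expression matrix and an annotation table."""
    cols = expr.values.columns
    missing = cols.difference(annot.index)
    if len(missing):
        raise ValidationError(f"samples missing from annotation table: {missing.tolist()[:5]}")
    annot = annot.loc[cols]
    expr = ExpressionMatrix(
        expr.values,
        annot["platform"] if "platform" in annot.columns else expr.platform,
        annot["dataset"] if "dataset" in annot.columns else expr.dataset,
    )
    return LabeledCohort(expr, annot["class"])


# ---------------------------------------------------------------------------
# Transforms and cohort surgery
# ---------------------------------------------------------------------------

def rank_transform(x: ExpressionMatrix) -> RankedMatrix:
    """Column-wise (within-sample) ranks; ties receive the average rank.

    Ranking each sample independently removes the per-sample scale entirely:
    the output is invariant under any strictly increasing transform applied
    per sample, which is the property that makes rank-trained models
    single-sample predictors.
    """
    ranked = rankdata(x.values.to_numpy(), method="average", axis=0)
    return RankedMatrix(
        pd.DataFrame(ranked, index=x.values.index, columns=x.values.columns),
        x.platform,
        x.dataset,
    )


def combine_cohorts(
    cohorts: Sequence[LabeledCohort],
    *,
    gene_mode: str = "intersection",
    dataset_names: Iterable[str] | None = None,
) -> LabeledCohort:
    """Concatenate cohorts sample-wise into a single labeled cohort.

    Gene sets are reconciled per ``gene_mode``: ``"intersection"`` (default)
    keeps the shared genes and warns about how many were dropped;
    ``"strict"`` requires identical gene sets.  The ``dataset`` metadata field
    records each sample's cohort of origin.
    """
    if not cohorts:
        raise ValueError("no cohorts to combine")
    names = list(dataset_names) if dataset_names is not None else [f"dataset_{i + 1}" for i in range(len(cohorts))]
    gene_sets = [pd.Index(c.expression.gene_ids) for c in cohorts]
    shared = gene_sets[0]
    for g in gene_sets[1:]:
        shared = shared.intersection(g)
    if gene_mode == "strict":
        if any(len(g) != len(shared) for g in gene_sets):
            raise ValidationError("cohorts have differing gene sets (gene_mode='strict')")
    elif gene_mode == "intersection":
        if len(shared) == 0:
            raise ValidationError("gene intersection across cohorts is empty")
        n_dropped = sum(len(g) - len(shared) for g in gene_sets)
        if n_dropped:
            warnings.warn(f"combine_cohorts: dropped {n_dropped} non-shared gene rows", stacklevel=2)
    else:
        raise ValueError(f"unknown gene_mode: {gene_mode!r}")
    # preserve the first cohort's gene order
    shared = gene_sets[0][gene_sets[0].isin(shared)]

    values = pd.concat([c.expression.values.loc[shared] for c in cohorts], axis=1)
    _check_unique(values.columns, "sample ids (across cohorts)")
    platform = pd.concat(
        [
            c.expression.platform
            if c.expression.platform is not None
            else pd.Series(name, index=c.expression.values.columns)
            for c, name in zip(cohorts, names)
        ]
    )
    dataset = pd.concat([pd.Series(name, index=c.expression.values.columns) for c, name in zip(cohorts, names)])
    labels = pd.concat([c.labels for c in cohorts])
    return LabeledCohort(ExpressionMatrix(values, platform, dataset), labels)


def stratified_split(
    cohort: LabeledCohort, train_fraction: float, seed: int
) -> tuple[LabeledCohort, LabeledCohort]:
    """Deterministic, exhaustive, disjoint train/test partition stratified by class.

    Per-class proportions are preserved to within rounding; every class must
    contribute at least one sample to each side, which requires >= 2 samples
    per class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    small = cohort.class_counts()[cohort.class_counts() < 2]
    if len(small):
        raise ValidationError(f"classes with < 2 samples cannot be split: {small.index.tolist()}")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in cohort.classes:
        ids = cohort.labels.index[cohort.labels == cls].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    # keep original column order for reproducible downstream matrices
    order = {s: i for i, s in enumerate(cohort.expression.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return cohort.subset(train_ids), cohort.subset(test_ids)
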