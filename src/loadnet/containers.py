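"""Shared data containers for the analysis pipeline.

Thin, validated wrappers around pandas objects: an expression matrix
(genes x samples), a clinical trait table (samples x traits) and a
genotype dosage matrix (variants x samples) with variant metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "TraitTable", "GenotypeMatrix"]


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
        Raw (untransformed) matrices must be non-negative.
    transformed
        Whether the matrix has been log2-transformed.
    """

    values: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not self.transformed and (self.values.to_numpy() < 0).any():
            raise ValidationError("raw expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], transformed=self.transformed)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, transformed: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, transformed=transformed)


@dataclass
class TraitTable:
    """Per-sample clinical covariates plus a case/control class label.

    One row per sample; trait columns are numeric. The class label column
    (default ``"class"``) holds the strings ``"case"`` / ``"control"``.
    """

    values: pd.DataFrame
    class_column: str = "class"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate sample ids in trait table")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.values.columns if c != self.class_column]

    @property
    def traits(self) -> pd.DataFrame:
        """Numeric trait columns only (class label excluded)."""
        return self.values[self.trait_names]

    @property
    def class_labels(self) -> pd.Series | None:
        if self.class_column in self.values.columns:
            return self.values[self.class_column]
        return None

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, class_column: str = "class") -> "TraitTable":
        return cls(pd.read_csv(path, index_col="sample_id"), class_column=class_column)


@dataclass
class GenotypeMatrix:
    """Variant-by-sample additive dosage matrix with variant metadata.

    Dosages count alt alleles (0/1/2); missing calls are NaN. ``meta`` has
    one row per variant (index = variant id) with columns chrom, pos, ref,
    alt; positions are 1-based.
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValidationError("duplicate variant ids")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("dosages must be 0, 1, 2 or missing")
        if len(self.meta) and (self.meta["pos"] < 1).any():
            raise ValidationError("variant positions are 1-based")

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    def subset_variants(self, variants) -> "GenotypeMatrix":
        meta = self.meta.loc[variants] if len(self.meta) else self.meta
        return GenotypeMatrix(self.dosages.loc[variants], meta)
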