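"""Core data containers shared across the pipeline.

The pipeline moves four kinds of tabular data around: genotype dosages,
gene expression, immune-cell abundances, and the clinical table.  Dosage
and expression matrices carry positional annotation (needed for cis-window
construction and LD clustering) and are therefore wrapped in light
dataclasses; cell abundances and clinical data are plain ``pandas``
DataFrames checked by validator functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Allowed expression scales, in the only order transitions may occur.
EXPRESSION_SCALES = ("raw", "uq_normalized", "log2")

#: Treatment arms of the trial the cohort structure emulates.
ARMS = ("bevacizumab", "cetuximab")

#: Columns every clinical table must carry.
CLINICAL_COLUMNS = (
    "os_time", "event", "arm", "age", "gender", "braf_v600e", "all_ras", "batch",
)


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-gene annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.  Raw-scale
        values must be non-negative.
    gene_annotation
        DataFrame indexed by gene id with columns ``chrom`` and ``tss``
        (1-based transcription start site).  Must cover every gene row.
    scale
        One of :data:`EXPRESSION_SCALES`.  Transitions only ever go
        raw -> uq_normalized -> log2 (enforced by the preprocessing ops).
    """

    values: pd.DataFrame
    gene_annotation: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise DataError(f"unknown expression scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise DataError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample ids in expression matrix")
        missing = self.values.index.difference(self.gene_annotation.index)
        if len(missing):
            raise DataError(
                f"{len(missing)} genes lack annotation (e.g. {list(missing[:3])})"
            )
        for col in ("chrom", "tss"):
            if col not in self.gene_annotation.columns:
                raise DataError(f"gene annotation missing column {col!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.loc[list(genes)],
            gene_annotation=self.gene_annotation.loc[list(genes)],
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(samples)])


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele dosages in [0, 2] with SNP annotation.

    ``dosages`` may contain NaN for missing genotypes until QC imputes
    them.  ``snp_annotation`` is indexed by SNP id with columns ``chrom``,
    ``pos`` (1-based), ``ref``, ``alt`` and ``maf``.
    """

    dosages: pd.DataFrame
    snp_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.columns.has_duplicates:
            raise DataError("duplicate SNP ids")
        if self.dosages.index.has_duplicates:
            raise DataError("duplicate sample ids in genotypes")
        missing = self.dosages.columns.difference(self.snp_annotation.index)
        if len(missing):
            raise DataError(f"{len(missing)} SNPs lack annotation")
        for col in ("chrom", "pos"):
            if col not in self.snp_annotation.columns:
                raise DataError(f"snp annotation missing column {col!r}")
        if (self.snp_annotation["pos"] <= 0).any():
            raise DataError("SNP positions must be strictly positive (1-based)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[list(samples)], self.snp_annotation)

    def subset_snps(self, snps: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[list(snps)], self.snp_annotation.loc[list(snps)]
        )

    def check_maf_consistency(self, tol: float = 0.02) -> None:
        """Verify annotated MAF agrees with the dosage mean within ``tol``."""
        freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        delta = (maf - self.snp_annotation.loc[maf.index, "maf"]).abs()
        bad = delta[delta > tol]
        if len(bad):
            raise DataError(
                f"annotated MAF inconsistent with dosages for {len(bad)} SNPs "
                f"(max deviation {bad.max():.3f})"
            )


def validate_abundances(abund: pd.DataFrame) -> pd.DataFrame:
    """Check a samples x cell-type abundance matrix (all entries >= 0)."""
    if (abund.to_numpy() < 0).any():
        raise DataError("cell abundances must be non-negative")
    if abund.index.has_duplicates or abund.columns.has_duplicates:
        raise DataError("duplicate ids in abundance matrix")
    return abund


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample clinical table.

    Requires columns ``os_time`` (> 0, months), ``event`` (0/1), ``arm``
    (non-missing), plus the covariates ``age``, ``gender``, ``braf_v600e``,
    ``all_ras`` and ``batch``.  An optional ``cms`` column holds consensus
    molecular subtype labels (may be missing per sample).
    """
    for col in CLINICAL_COLUMNS:
        if col not in clinical.columns:
            raise DataError(f"clinical table missing column {col!r}")
    if (clinical["os_time"] <= 0).any():
        raise DataError("os_time must be strictly positive")
    if not clinical["event"].isin([0, 1]).all():
        raise DataError("event indicator must be 0/1")
    if clinical["arm"].isna().any():
        raise DataError("treatment arm must be non-missing")
    bad_arms = set(clinical["arm"].unique()) - set(ARMS)
    if bad_arms:
        raise DataError(f"unknown treatment arms {sorted(bad_arms)}")
    return clinical


@dataclass
class PairedExpression:
    """Aligned tumor/normal log2 expression for paired samples.

    ``tumor`` and ``normal`` are genes x pairs DataFrames whose columns
    (pair ids) correspond one-to-one.
    """

    tumor: pd.DataFrame
    normal: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.tumor.columns.equals(self.normal.columns):
            raise DataError("tumor and normal pair ids must align one-to-one")
        if not self.tumor.index.equals(self.normal.index):
            raise DataError("tumor and normal gene ids must align")

    @property
    def pair_ids(self) -> pd.Index:
        return self.tumor.columns

    @property
    def n_pairs(self) -> int:
        return self.tumor.shape[1]


@dataclass
class Cohort:
    """One cohort's worth of linked data.

    A discovery cohort carries expression and abundances; a genotype-only
    validation cohort leaves them ``None``.  ``truth`` holds the generative
    record (planted eQTL betas, causal genes, pleiotropic SNPs) when the
    cohort was simulated, and ``None`` for real data.
    """

    genotypes: GenotypeMatrix
    clinical: pd.DataFrame
    expression: Optional[ExpressionMatrix] = None
    abundances: Optional[pd.DataFrame] = None
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        validate_clinical(self.clinical)
        geno_samples = self.genotypes.sample_ids
        if not geno_samples.equals(pd.Index(self.clinical.index)):
            raise DataError("genotype and clinical sample ids differ or are reordered")
        if self.expression is not None:
            if list(self.expression.sample_ids) != list(geno_samples):
                raise DataError("expression sample ids differ from genotypes")
        if self.abundances is not None:
            validate_abundances(self.abundances)
            if list(self.abundances.index) != list(geno_samples):
                raise DataError("abundance sample ids differ from genotypes")

    @property
    def sample_ids(self) -> pd.Index:
        return self.genotypes.sample_ids

    @property
    def n(self) -> int:
        return len(self.sample_ids)
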