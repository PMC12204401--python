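"""Expression, genotype and cell-abundance filters and transformations.

Implements the preprocessing conventions of the analysis: variance/zero
filters on genes, upper-quartile normalization followed by the log2
transform, genotype QC (call rate, Hardy-Weinberg exact test, MAF, sample
call rate), the enriched-cell-type filter, a chromosome-Y k-means sex
check, and expression PCA.  Exclusion rules quoted with strict
inequalities are applied exactly as quoted ("<0.5" SD and ">30% zeros"
exclude; "at most 30%" keeps; ">0.12" SD keeps strictly).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .types import DataError, ExpressionMatrix, GenotypeMatrix

log = logging.getLogger(__name__)


def filter_genes(
    expr: ExpressionMatrix, sd_min: float = 0.5, zero_frac_max: float = 0.30
) -> ExpressionMatrix:
    """Drop low-variation and zero-heavy genes from a raw expression matrix.

    A gene survives iff its across-sample standard deviation (ddof=1) is
    at least ``sd_min`` and its fraction of zero entries is at most
    ``zero_frac_max``; both boundaries keep.  Row order is preserved.
    """
    if expr.scale != "raw":
        raise DataError("filter_genes expects raw-scale expression")
    v = expr.values
    sd = v.std(axis=1, ddof=1)
    zero_frac = (v == 0).mean(axis=1)
    keep = (sd >= sd_min) & (zero_frac <= zero_frac_max)
    if not keep.any():
        raise DataError("gene filter removed every gene")
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_genes: dropped %d of %d genes", dropped, len(keep))
    return expr.subset_genes(v.index[keep])


def normalize_expression(
    expr: ExpressionMatrix, zero_gene_frac_max: float = 0.5
) -> ExpressionMatrix:
    """Upper-quartile normalize each sample, then move to the log2 scale.

    Samples with more than ``zero_gene_frac_max`` zero genes are removed
    first (tumors with globally low expression).  Each remaining sample is
    divided by the 75th percentile of its nonzero values and rescaled by
    the global mean of those upper quartiles, so per-sample upper
    quartiles agree afterwards; finally values become log2(x + 1).
    """
    if expr.scale != "raw":
        raise DataError("normalize_expression expects raw-scale expression")
    v = expr.values
    zero_frac = (v == 0).mean(axis=0)
    drop = zero_frac > zero_gene_frac_max
    if drop.all():
        raise DataError("every sample exceeds the zero-gene fraction limit")
    if drop.any():
        log.info(
            "normalize_expression: removed %d samples with >%.0f%% zero genes",
            int(drop.sum()), 100 * zero_gene_frac_max,
        )
        v = v.loc[:, ~drop]
    uq = v.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan)
    if uq.isna().any():
        bad = list(uq.index[uq.isna()][:3])
        raise DataError(f"samples with all-zero expression: {bad}")
    scaled = v.div(uq, axis=1) * uq.mean()
    out = np.log2(scaled + 1.0)
    return ExpressionMatrix(out, expr.gene_annotation.loc[out.index], scale="log2")


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value (two-sided, mid-less).

    Enumerates the conditional distribution of the heterozygote count
    given allele counts and sums the probabilities of all configurations
    no more likely than the observed one (the standard exact HWE test).
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0
    n_minor = min(n_minor, 2 * n - n_minor)
    # log-probability of each feasible heterozygote count (same parity as n_minor)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min


    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
        + hets * np.log(2.0)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_het
    p_obs = p[hets == obs]
    if len(p_obs) == 0:  # impossible het count given allele parity
        return 0.0
    return float(min(p[p <= p_obs[0] * (1 + 1e-12)].sum(), 1.0))


def qc_genotypes(
    geno: GenotypeMatrix,
    snp_call_min: float = 0.99,
    hwe_p_min: float = 1e-8,
    maf_min: float = 0.05,
    sample_call_min: float = 0.90,
) -> GenotypeMatrix:
    """Genotype QC: SNP call rate, HWE exact test, MAF, then sample call rate.

    SNPs failing call rate < ``snp_call_min``, HWE exact p < ``hwe_p_min``
    or MAF < ``maf_min`` are dropped; afterwards samples with call rate
    below ``sample_call_min`` (on the retained SNPs) are dropped.  Both
    passes run once, in that order, with no iteration.  Remaining missing
    dosages are mean-imputed per SNP and the annotated MAF refreshed.
    """
    dos = geno.dosages
    call = dos.notna().mean(axis=0)
    freq = dos.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    hwe_p = pd.Series(1.0, index=dos.columns)
    rounded = dos.round()
    for snp in dos.columns:
        col = rounded[snp].dropna()
        n_hom_a = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom_b = int((col == 2).sum())
        # orient to minor allele
        if 2 * n_hom_b + n_het <= 2 * n_hom_a + n_het:
            hwe_p[snp] = hwe_exact_p(n_het, n_hom_b, n_hom_a)
        else:
            hwe_p[snp] = hwe_exact_p(n_het, n_hom_a, n_hom_b)

    keep_snp = (call >= snp_call_min) & (hwe_p >= hwe_p_min) & (maf >= maf_min)
    log.info(
        "qc_genotypes: dropped %d SNPs (call %d, HWE %d, MAF %d, overlaps possible)",
        int((~keep_snp).sum()), int((call < snp_call_min).sum()),
        int((hwe_p < hwe_p_min).sum()), int((maf < maf_min).sum()),
    )
    dos = dos.loc[:, keep_snp]

    sample_call = dos.notna().mean(axis=1) if dos.shape[1] else pd.Series(1.0, index=dos.index)
    keep_sample = sample_call >= sample_call_min
    if (~keep_sample).any():
        log.info("qc_genotypes: dropped %d samples by call rate", int((~keep_sample).sum()))
    dos = dos.loc[keep_sample]

    dos = dos.fillna(dos.mean(axis=0))
    ann = geno.snp_annotation.loc[dos.columns].copy()
    new_freq = dos.mean(axis=0) / 2.0
    ann["maf"] = np.minimum(new_freq, 1.0 - new_freq)
    return GenotypeMatrix(dos, ann)


def filter_cell_types(
    abund: pd.DataFrame, zero_frac_max: float = 0.30, sd_min: float = 0.12
) -> pd.DataFrame:
    """Keep cell types whose scores are nonzero in >=70% of samples and
    spread with standard deviation strictly above ``sd_min``."""
    zero_frac = (abund == 0).mean(axis=0)
    sd = abund.std(axis=0, ddof=1)
    keep = (zero_frac <= zero_frac_max) & (sd > sd_min)
    dropped = list(abund.columns[~keep])
    if dropped:
        log.info("filter_cell_types: dropped %s", dropped)
    return abund.loc[:, keep]


def infer_genetic_sex(
    expr: ExpressionMatrix,
    chry_genes: Sequence[str],
    recorded_gender: Optional[pd.Series] = None,
) -> Tuple[pd.Series, pd.DataFrame]:
    """2-means clustering on chromosome-Y expression to label genetic sex.

    The cluster with the higher mean chrY expression is labelled male (1).
    Returns per-sample labels plus a mismatch report against
    ``recorded_gender`` (empty when no gender is supplied).  A degenerate
    clustering (all samples identical) yields all-male-or-female labels
    with a ``degenerate`` flag in the report's attrs and asserts no
    mismatches.
    """
    if expr.scale != "log2":
        raise DataError("infer_genetic_sex expects log2-scale expression")
    chry = [g for g in chry_genes if g in expr.gene_ids]
    if len(chry) < 2:
        raise DataError("need at least two chrY genes for the sex check")
    sub = expr.values.loc[chry].T  # samples x genes
    if np.allclose(sub.to_numpy().std(axis=0), 0):
        labels = pd.Series(0, index=sub.index, name="genetic_sex")
        report = pd.DataFrame(columns=["recorded", "inferred"])
        report.attrs["degenerate"] = True
        return labels, report
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(sub.to_numpy())
    cluster_means = [sub.to_numpy()[km.labels_ == c].mean() for c in (0, 1)]
    male_cluster = int(np.argmax(cluster_means))
    labels = pd.Series(
        (km.labels_ == male_cluster).astype(int), index=sub.index, name="genetic_sex"
    )
    report = pd.DataFrame(columns=["recorded", "inferred"])
    if recorded_gender is not None:
        rec = recorded_gender.reindex(labels.index)
        mism = labels.index[(rec != labels) & rec.notna()]
        report = pd.DataFrame(
            {"recorded": rec.loc[mism], "inferred": labels.loc[mism]}
        )
    report.attrs["degenerate"] = False
    return labels, report


def pca_expression(expr: ExpressionMatrix, k: int) -> pd.DataFrame:
    """Top-k principal-component scores of the gene-centered log2 matrix.

    Components are sign-fixed so each one's largest-magnitude gene loading
    is positive, making scores reproducible across runs.
    """
    if expr.scale != "log2":
        raise DataError("pca_expression expects log2-scale expression")
    n_genes, n_samples = expr.values.shape
    if k > min(n_genes, n_samples):
        raise DataError(f"k={k} exceeds matrix rank bound {min(n_genes, n_samples)}")
    if k == 0:
        return pd.DataFrame(index=expr.sample_ids)
    X = expr.values.T.to_numpy()  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| gene positive per component
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )


def build_covariates(
    clinical: pd.DataFrame,
    abundances: Optional[pd.DataFrame] = None,
    batch_dummies: bool = True,
) -> pd.DataFrame:
    """Assemble the model covariate matrix Z (and E when supplied).

    Includes gender, age, BRAF V600E and all-RAS status, batch indicator
    columns (first batch as reference), and the enriched cell-type
    abundances.  Compositional abundance sets that sum to a constant are
    released from closure by dropping the final column (otherwise they are
    collinear with the model intercept).
    """
    cov = pd.DataFrame(
        {
            "gender": clinical["gender"].astype(float),
            "age": clinical["age"].astype(float),
            "braf_v600e": clinical["braf_v600e"].astype(float),
            "all_ras": clinical["all_ras"].astype(float),
        },
        index=clinical.index,
    )
    if batch_dummies and clinical["batch"].nunique() > 1:
        dummies = pd.get_dummies(clinical["batch"], prefix="batch", drop_first=True)
        cov = pd.concat([cov, dummies.astype(float)], axis=1)
    if abundances is not None and abundances.shape[1] > 0:
        ab = abundances.reindex(cov.index)
        rowsum = ab.sum(axis=1)
        if ab.shape[1] > 1 and np.allclose(rowsum, rowsum.iloc[0], atol=1e-8):
            log.info("build_covariates: dropping %s to break compositional closure",
                     ab.columns[-1])
            ab = ab.iloc[:, :-1]
        cov = pd.concat([cov, ab], axis=1)
    return cov
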