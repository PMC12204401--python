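"""cis-eQTL mapping with permutation-based gene-level p-values.

Per gene, expression is regressed on each cis SNP (within +/- 1 Mb of the
TSS, both ends inclusive) with covariate adjustment; the gene-level
adjusted p-value comes from permuting covariate residuals (Freedman-Lane
style) and comparing the best permuted association against the best
observed one:

    adjusted_p = (1 + #{permutation best >= observed best}) / (1 + n_perm)

so values honor the 1/(n_perm + 1) floor.  The marginal per-SNP betas of
the scan are the weights the one-sample Mendelian-randomization stage
uses for predicted expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DataError, ExpressionMatrix, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000


@dataclass
class EqtlTable:
    """Nominal pair-level statistics plus per-gene permutation summaries.

    ``pairs`` has one row per tested (gene, SNP) pair: beta (log2
    expression per allele), se, nominal_p.  ``genes`` has one row per gene
    with the best SNP, its nominal p, the permutation-adjusted p and the
    number of permutations actually used (NaN before
    :func:`map_egenes` runs).
    """

    pairs: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def weights_for(self, gene: str, snps: Sequence[str]) -> pd.Series:
        sub = self.pairs[(self.pairs.gene == gene) & self.pairs.snp.isin(snps)]
        return sub.set_index("snp")["beta"].reindex(snps)


def build_cis_pairs(
    gene_annotation: pd.DataFrame,
    snp_annotation: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> pd.DataFrame:
    """All (gene, SNP) pairs with |pos - TSS| <= window on the same chromosome.

    The window is inclusive at both ends.  Returns a DataFrame with
    columns gene, snp, distance (signed, pos - TSS).
    """
    out = []
    snp_by_chrom = {c: sub for c, sub in snp_annotation.groupby("chrom")}
    for gene, row in gene_annotation.iterrows():
        snps = snp_by_chrom.get(row["chrom"])
        if snps is None:
            continue
        dist = snps["pos"].to_numpy() - int(row["tss"])
        hit = np.abs(dist) <= window
        if hit.any():
            out.append(pd.DataFrame({
                "gene": gene, "snp": snps.index[hit], "distance": dist[hit],
            }))
    if not out:
        return pd.DataFrame(columns=["gene", "snp", "distance"])
    return pd.concat(out, ignore_index=True)


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of Y on the covariate matrix C (incl. intercept)."""
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ coef


def _check_covariates(covariates: pd.DataFrame) -> np.ndarray:
    C = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = [0]
        for j in range(1, C.shape[1]):
            if np.linalg.matrix_rank(C[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(covariates.columns[j - 1])
        raise DataError(f"collinear covariate columns: {bad}")
    return C


def nominal_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    pairs: pd.DataFrame,
) -> EqtlTable:
    """Per-pair OLS of expression on dosage plus covariates.

    Equivalent to the full regression by Frisch-Waugh: both expression and
    dosage are residualized on the covariates (with intercept) and the
    slope of residual on residual is tested with a t-statistic on
    n - n_covariates - 2 degrees of freedom.  Pairs whose dosage is
    constant after residualization are skipped with a log entry.
    """
    if expr.scale != "log2":
        raise DataError("nominal_scan expects log2-scale expression")
    samples = expr.sample_ids
    if list(samples) != list(geno.sample_ids) or list(samples) != list(covariates.index):
        raise DataError("expression, genotype and covariate samples must align")
    C = _check_covariates(covariates)
    n = len(samples)
    dof = n - C.shape[1] - 1
    if dof <= 0:
        raise DataError("not enough samples for the covariate-adjusted scan")

    genes = pairs["gene"].unique()
    Y = _residualize(expr.values.loc[genes].T.to_numpy(float), C)  # samples x genes
    D = _residualize(geno.dosages.to_numpy(float), C)              # samples x snps
    gene_pos = {g: i for i, g in enumerate(genes)}
    snp_pos = {s: i for i, s in enumerate(geno.snp_ids)}

    rows = []
    skipped = 0
    for gene, snp in pairs[["gene", "snp"]].itertuples(index=False):
        ry = Y[:, gene_pos[gene]]
        rd = D[:, snp_pos[snp]]
        dd = rd @ rd
        if dd < 1e-12:
            skipped += 1
            continue
        beta = (rd @ ry) / dd
        rss = ry @ ry - beta**2 * dd
        se = np.sqrt(max(rss, 0.0) / dof / dd)
        tstat = beta / se if se > 0 else np.inf
        p = 2 * stats.t.sf(abs(tstat), dof)
        rows.append((gene, snp, beta, se, max(p, np.nextafter(0, 1))))
    if skipped:
        log.info("nominal_scan: skipped %d pairs with constant dosage", skipped)
    table = pd.DataFrame(rows, columns=["gene", "snp", "beta", "se", "nominal_p"])
    genes_df = (
        table.loc[table.groupby("gene")["nominal_p"].idxmin()]
        .set_index("gene")[["snp", "nominal_p"]]
        .rename(columns={"snp": "best_snp", "nominal_p": "best_p"})
    )
    genes_df["adjusted_p"] = np.nan
    genes_df["n_perm"] = np.nan
    return EqtlTable(pairs=table, genes=genes_df)


def permutation_gene_pvalue(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    gene: str,
    cis_snps: Sequence[str],
    n_perm: int = 10_000,
    adaptive: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Gene-level adjusted p-value by residual permutation.

    Covariate residuals of the gene's expression are permuted across
    samples; each permutation's best |correlation| against the (covariate-
    residualized) cis dosages is compared with the observed best.  In
    adaptive mode permutation stops once 100 exceedances have accumulated.

    Returns ``(adjusted_p, n_perm_used)``.
    """
    if n_perm < 100:
        raise DataError("n_perm must be at least 100")
    if len(cis_snps) == 0:
        raise DataError(f"gene {gene} has no cis SNPs")
    rng = rng if rng is not None else np.random.default_rng(0)
    C = _check_covariates(covariates)
    ry = _residualize(expr.values.loc[[gene]].T.to_numpy(float), C)[:, 0]
    D = _residualize(geno.dosages[list(cis_snps)].to_numpy(float), C)
    keep = D.std(axis=0) > 1e-8
    D = D[:, keep]
    if D.shape[1] == 0:
        raise DataError(f"gene {gene}: all cis dosages constant")
    Dn = D / np.linalg.norm(D, axis=0)
    ryn = ry / np.linalg.norm(ry)
    obs = np.max(np.abs(ryn @ Dn))

    batch = 500
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = rng.permuted(np.tile(ryn, (b, 1)), axis=1)  # b independent shuffles
        best = np.max(np.abs(P @ Dn), axis=1)
        exceed += int(np.sum(best >= obs))
        done += b
        if adaptive and exceed >= 100:
            break
    return (1 + exceed) / (1 + done), done


def map_egenes(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    pairs: pd.DataFrame,
    n_perm: int = 1_000,
    adaptive: bool = True,
    seed: int = 0,
) -> EqtlTable:
    """Nominal scan plus per-gene permutation p-values for every gene in pairs."""
    table = nominal_scan(expr, geno, covariates, pairs)
    rng = np.random.default_rng(seed)
    adj, used = {}, {}
    for gene, sub in pairs.groupby("gene"):
        if gene not in table.genes.index:
            continue
        adj[gene], used[gene] = permutation_gene_pvalue(
            expr, geno, covariates, gene, list(sub["snp"]),
            n_perm=n_perm, adaptive=adaptive, rng=rng,
        )
    table.genes["adjusted_p"] = pd.Series(adj)
    table.genes["n_perm"] = pd.Series(used)
    return table


def select_egenes(table: EqtlTable, alpha: float = 0.05) -> list:
    """Genes whose permutation-adjusted p-value is strictly below alpha."""
    g = table.genes
    if g.empty:
        return []
    return list(g.index[g["adjusted_p"] < alpha])
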