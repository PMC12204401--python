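"""Post-MR analyses: CMS enrichment, paired DE, prognostic LRT, KM curves.

Expression of each causal gene is dichotomized at the study-wide median
into "beneficial" / "non-beneficial" according to the sign of its causal
effect on survival (higher expression of a protective gene is
beneficial; for a harmful gene the labels flip).  A consensus molecular
subtype is called enriched when strictly more than 70% of its patients
fall on one side.  Paired tumor/normal differential expression uses a
paired t-test on log2 differences; the prognostic contribution of
biomarkers is a Cox likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .survival import (
    KMCurves,
    fit_cox,
    kaplan_meier,
    likelihood_ratio_test,
)
from .types import DataError, ExpressionMatrix, PairedExpression

log = logging.getLogger(__name__)

CMS_LEVELS = ("CMS1", "CMS2", "CMS3", "CMS4")


@dataclass
class EnrichmentResult:
    """Per-subtype beneficial/non-beneficial fractions for one gene."""

    gene: str
    fractions: pd.DataFrame      # subtypes x [beneficial, non_beneficial, n]
    enriched: Dict[str, str]     # subtype -> beneficial | non-beneficial | none
    direction: str               # protective | harmful


def classify_beneficial(
    expr: ExpressionMatrix, gene: str, causal_direction: str
) -> pd.Series:
    """Label each sample beneficial/non-beneficial by median-split expression.

    ``causal_direction`` is ``"protective"`` (higher expression lengthens
    survival: above-median is beneficial) or ``"harmful"`` (the reverse).
    The median is computed study-wide over all samples; at-median values
    count as below-median.  A constant gene leaves every sample on one
    side; the returned series then carries ``degenerate=True`` in attrs.
    """
    if causal_direction not in ("protective", "harmful"):
        raise DataError("causal_direction must be 'protective' or 'harmful'")
    x = expr.values.loc[gene]
    med = float(x.median())
    above = x > med
    if causal_direction == "protective":
        labels = np.where(above, "beneficial", "non-beneficial")
    else:
        labels = np.where(above, "non-beneficial", "beneficial")
    out = pd.Series(labels, index=x.index, name=f"{gene}_benefit")
    out.attrs["degenerate"] = bool(x.nunique() == 1)
    return out


def cms_enrichment(
    labels: pd.Series,
    cms: pd.Series,
    threshold: float = 0.70,
    gene: str = "",
    direction: str = "",
) -> EnrichmentResult:
    """Call subtypes enriched when > ``threshold`` of patients share a label.

    The rule is strict: a fraction exactly at the threshold is not
    enriched.  Subtypes absent from ``cms`` get label ``none`` with a log
    entry.
    """
    cms = cms.reindex(labels.index)
    rows = {}
    enriched = {}
    for subtype in CMS_LEVELS:
        mask = cms == subtype
        n = int(mask.sum())
        if n == 0:
            log.info("cms_enrichment: subtype %s absent", subtype)
            rows[subtype] = (np.nan, np.nan, 0)
            enriched[subtype] = "none"
            continue
        frac_ben = float((labels[mask] == "beneficial").mean())
        rows[subtype] = (frac_ben, 1.0 - frac_ben, n)
        if frac_ben > threshold:
            enriched[subtype] = "beneficial"
        elif 1.0 - frac_ben > threshold:
            enriched[subtype] = "non-beneficial"
        else:
            enriched[subtype] = "none"
    fractions = pd.DataFrame(
        rows, index=["beneficial", "non_beneficial", "n"]
    ).T.astype({"n": int})
    return EnrichmentResult(
        gene=gene, fractions=fractions, enriched=enriched, direction=direction
    )


def paired_de(paired: PairedExpression, gene: str) -> Tuple[float, float]:
    """Tumor-vs-normal fold change and paired t-test p for one gene.

    Returns ``(fold_change, p)`` where the fold change is
    2**mean(log2 tumor - log2 normal).  With identical tumor and normal
    values the t statistic is undefined and p is reported as 1.  Fails
    below 2 pairs (no degrees of freedom for the test).
    """
    if paired.n_pairs < 2:
        raise DataError("paired differential expression needs at least 2 pairs")
    diff = (paired.tumor.loc[gene] - paired.normal.loc[gene]).to_numpy(float)
    fc = float(2.0 ** diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
    else:
        p = float(stats.ttest_1samp(diff, 0.0).pvalue)
    return fc, p


def paired_de_wilcoxon(paired: PairedExpression, gene: str) -> Tuple[float, float]:
    """Wilcoxon signed-rank alternative to :func:`paired_de`."""
    if paired.n_pairs < 2:
        raise DataError("paired differential expression needs at least 2 pairs")
    diff = (paired.tumor.loc[gene] - paired.normal.loc[gene]).to_numpy(float)
    fc = float(2.0 ** diff.mean())
    if np.allclose(diff, 0.0):
        return fc, 1.0
    return fc, float(stats.wilcoxon(diff).pvalue)


def prognostic_lrt(
    clinical: pd.DataFrame,
    biomarkers: pd.DataFrame,
    arm: str,
    covariates: pd.DataFrame,
) -> Tuple[float, int, float]:
    """Cox LRT of the survival model with vs without the biomarker columns.

    Both models are fitted on the arm's subset with the shared covariates;
    the degrees of freedom equal the number of biomarkers added.  Returns
    ``(chi2, df, p)``; zero biomarkers give chi2 = 0, p = 1.
    """
    mask = clinical["arm"] == arm
    clin = clinical.loc[mask]
    cov = covariates.reindex(clin.index)
    bio = biomarkers.reindex(clin.index)
    reduced = fit_cox(clin["os_time"], clin["event"], cov)
    if bio.shape[1] == 0:
        return 0.0, 0, 1.0
    full = fit_cox(clin["os_time"], clin["event"], pd.concat([cov, bio], axis=1))
    return likelihood_ratio_test(full, reduced)


def km_by_median(
    expr_values: pd.Series,
    clinical: pd.DataFrame,
    arm: str,
    split: str = "arm",
) -> KMCurves:
    """Kaplan-Meier curves for high vs low expression within a treatment arm.

    ``split`` chooses whether the median cutoff comes from the arm's
    samples (default) or the whole study (``"study"``); ties go to the
    low group.  Fails when the split leaves an empty group (constant
    expression).
    """
    mask = clinical["arm"] == arm
    clin = clinical.loc[mask]
    x = expr_values.reindex(clin.index)
    med = float(x.median() if split == "arm" else expr_values.median())
    group = np.where(x > med, "high", "low")
    if len(np.unique(group)) < 2:
        raise DataError("median split produced a single group (constant expression)")
    return kaplan_meier(clin["os_time"], clin["event"], group)
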