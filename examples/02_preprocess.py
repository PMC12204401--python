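"""Expression and genotype preprocessing on raw simulated counts.

Applies the variance/zero gene filter, upper-quartile + log2
normalization, genotype QC (call rate, exact Hardy-Weinberg, MAF), the
enriched-cell-type filter and the chromosome-Y sex check.  The counts
printed are how many genes/SNPs/cell types survive each rule.
"""

from mrhaz import SimConfig, make_cohort
from mrhaz.preprocess import (
    filter_cell_types, filter_genes, infer_genetic_sex,
    normalize_expression, qc_genotypes,
)

config = SimConfig(n_discovery=300, n_validation=0, n_genes=40, n_egenes=20,
                   n_sex_mismatches=3, seed=2)
discovery, _ = make_cohort(config)

counts = discovery.truth["counts"]          # raw-scale Poisson counts
filtered = filter_genes(counts)
log2 = normalize_expression(filtered)
print(f"gene filter: {counts.values.shape[0]} -> {filtered.values.shape[0]} genes")
print(f"normalized to log2 scale: {log2.scale}")

qc = qc_genotypes(discovery.genotypes)
print(f"genotype QC: {discovery.genotypes.dosages.shape[1]} -> "
      f"{qc.dosages.shape[1]} SNPs")

enriched = filter_cell_types(discovery.abundances)
print(f"enriched cell types: {enriched.shape[1]} of "
      f"{discovery.abundances.shape[1]}")

chry = [g for g in discovery.expression.gene_ids if g.startswith("GY")]
labels, report = infer_genetic_sex(discovery.expression, chry,
                                   discovery.clinical["gender"])
print(f"sex check: {len(report)} samples with mismatched recorded gender "
      "(3 were planted)")
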