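"""File formats, configuration and cohort assembly.

Formats are deliberately plain: tab-separated text for expression
(first column ``gene_id``, header row of sample ids), abundances and
clinical tables; BED-like 4-column gene annotation (chrom, tss, tss,
gene_id; 1-based inclusive); genotypes as a minimal VCF with a GT field
or as a dosage TSV; the simulation truth record as a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    Cohort,
    DataError,
    ExpressionMatrix,
    GenotypeMatrix,
    validate_clinical,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# expression / annotation / clinical / abundances
# --------------------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path, annotation: pd.DataFrame, scale: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.columns.name = "sample_id"
    return ExpressionMatrix(df, annotation.loc[df.index], scale=scale)


def write_gene_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """BED-like 4 columns: chrom, tss, tss, gene_id (1-based inclusive)."""
    out = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"].astype(int),
            "end": annotation["tss"].astype(int),
            "gene_id": annotation.index,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gene_annotation_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"])
    ann = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "tss": df["start"].to_numpy(int)},
        index=pd.Index(df["gene_id"], name="gene_id"),
    )
    return ann


def write_table_tsv(df: pd.DataFrame, path, index_name: str = "sample_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_table_tsv(path, index_name: str = "sample_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_name)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal biallelic VCF with a GT field (dosages rounded to 0/1/2)."""
    ann = geno.snp_annotation
    samples = list(geno.sample_ids)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dos = geno.dosages
        for snp in geno.snp_ids:
            row = ann.loc[snp]
            calls = []
            for v in dos[snp].to_numpy():
                calls.append("./." if np.isnan(v) else gt_map[int(round(v))])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                f"{row.get('ref', 'A')}\t{row.get('alt', 'G')}\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Parse a GT-only VCF into a dosage matrix.

    Malformed lines fail with their 1-based line number.
    """
    samples: list = []
    snp_rows = []
    dosage_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise DataError(f"VCF line {lineno}: header has no samples")
                samples = fields[9:]
                continue
            if not samples:
                raise DataError(f"VCF line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise DataError(
                    f"VCF line {lineno}: expected {9 + len(samples)} fields, "
                    f"got {len(fields)}"
                )
            chrom, pos, snp_id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "GT" not in fields[8].split(":"):
                raise DataError(f"VCF line {lineno}: FORMAT lacks GT")
            gt_index = fields[8].split(":").index("GT")
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise DataError(f"VCF line {lineno}: bad POS {pos!r}") from exc
            doses = []
            for sample_field in fields[9:]:
                gt = sample_field.split(":")[gt_index].replace("|", "/")
                if gt in (".", "./."):
                    doses.append(np.nan)
                    continue
                try:
                    a, b = gt.split("/")
                    doses.append(float(int(a) + int(b)))
                except ValueError as exc:
                    raise DataError(f"VCF line {lineno}: bad GT {gt!r}") from exc
            snp_rows.append((snp_id, chrom, pos_i, ref, alt))
            dosage_rows.append(doses)
    if not snp_rows:
        raise DataError("VCF contains no variant records")
    ann = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    ).set_index("snp_id")
    dos = pd.DataFrame(
        np.asarray(dosage_rows, dtype=float).T,
        index=pd.Index(samples, name="sample_id"),
        columns=ann.index.copy(),
    )
    dos.columns.name = None
    freq = dos.mean(axis=0, skipna=True) / 2.0
    ann["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dos, ann)


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    """Dosage TSV: snp_id, chrom, pos, ref, alt, then one column per sample."""
    ann = geno.snp_annotation[["chrom", "pos", "ref", "alt"]].copy()
    merged = pd.concat([ann, geno.dosages.T], axis=1)
    merged.index.name = "snp_id"
    merged.to_csv(path, sep="\t")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    ann = df[meta_cols].copy()
    dos = df.drop(columns=meta_cols).T.astype(float)
    dos.index.name = "sample_id"
    dos.columns.name = None
    freq = dos.mean(axis=0, skipna=True) / 2.0
    ann["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dos, ann)


# --------------------------------------------------------------------------
# truth sidecar
# --------------------------------------------------------------------------

def write_truth_json(truth: dict, path) -> None:
    """Serialize the generative truth record (betas, causal genes, ...)."""

    def enc(obj):
        if isinstance(obj, pd.Series):
            return {"index": list(obj.index), "values": [float(v) for v in obj]}
        if isinstance(obj, pd.DataFrame):
            return {"columns": list(obj.columns),
                    "index": list(obj.index),
                    "values": obj.to_numpy().tolist()}
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, default=enc, indent=1)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir, prefix: str = "cohort") -> dict:
    """Write every component of a cohort; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["vcf"] = out / f"{prefix}.genotypes.vcf"
    write_vcf(cohort.genotypes, paths["vcf"])
    paths["dosages"] = out / f"{prefix}.dosages.tsv"
    write_dosage_tsv(cohort.genotypes, paths["dosages"])
    paths["clinical"] = out / f"{prefix}.clinical.tsv"
    write_table_tsv(cohort.clinical, paths["clinical"])
    if cohort.expression is not None:
        paths["expression"] = out / f"{prefix}.expression.tsv"
        write_expression_tsv(cohort.expression, paths["expression"])
        paths["gene_annotation"] = out / f"{prefix}.genes.bed"
        write_gene_annotation_bed(cohort.expression.gene_annotation, paths["gene_annotation"])
    if cohort.abundances is not None:
        paths["abundances"] = out / f"{prefix}.abundances.tsv"
        write_table_tsv(cohort.abundances, paths["abundances"])
    if cohort.truth is not None:
        paths["truth"] = out / f"{prefix}.truth.json"
        slim = {
            k: v for k, v in cohort.truth.items()
            if k in ("eqtl_betas", "egenes", "causal_genes",
                     "pleiotropic_snps", "cms_genes")
        }
        write_truth_json(slim, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def load_cohort(
    genotypes,
    clinical,
    expression=None,
    gene_annotation=None,
    abundances=None,
    expression_scale: str = "log2",
) -> Cohort:
    """Assemble a cohort from files, intersecting sample ids across inputs.

    Samples absent from any supplied component are dropped with a logged
    count; an empty intersection fails.  ``genotypes`` may be a VCF
    (``.vcf``) or a dosage TSV.
    """
    geno = read_vcf(genotypes) if str(genotypes).endswith(".vcf") else read_dosage_tsv(genotypes)
    clin = read_table_tsv(clinical)
    shared = geno.sample_ids.intersection(clin.index)

    expr = None
    if expression is not None:
        if gene_annotation is None:
            raise DataError("expression requires a gene annotation file")
        ann = read_gene_annotation_bed(gene_annotation)
        expr = read_expression_tsv(expression, ann, scale=expression_scale)
        shared = shared.intersection(expr.sample_ids)
    abund = None
    if abundances is not None:
        abund = read_table_tsv(abundances)
        shared = shared.intersection(abund.index)

    if len(shared) == 0:
        raise DataError("no samples shared across the supplied inputs")
    n_union = len(set(geno.sample_ids) | set(clin.index))
    dropped = n_union - len(shared)
    if dropped:
        log.info("load_cohort: dropped %d samples outside the intersection", dropped)
    shared = [s for s in geno.sample_ids if s in set(shared)]  # keep genotype order
    return Cohort(
        genotypes=geno.subset_samples(shared),
        clinical=validate_clinical(clin.loc[shared]),
        expression=expr.subset_samples(shared) if expr is not None else None,
        abundances=abund.loc[shared] if abund is not None else None,
    )


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, serializable to YAML losslessly."""

    seed: int = 0
    out_dir: str = "mrhaz_out"
    # simulation (used when no input paths are given)
    simulate: dict = field(default_factory=dict)
    # input paths (optional; override simulation)
    inputs: dict = field(default_factory=dict)
    # stage thresholds — defaults are the analysis' published values
    cis_window: int = 1_000_000
    n_perm: int = 1_000
    alpha_egene: float = 0.05
    alpha_screen: float = 0.10
    alpha_causal: float = 0.05
    p_nominal: float = 0.05
    r2_max: float = 0.10
    pleiotropy_p: float = 1e-4
    corr_min: float = 0.5
    k_clusters: int = 4
    # stage toggles
    run_eqtl: bool = True
    run_mr_stage: bool = True
    run_twosample: bool = True
    run_downstream: bool = True

    def validate(self) -> None:
        for name in ("alpha_egene", "alpha_screen", "alpha_causal", "p_nominal",
                     "pleiotropy_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise DataError(f"{name} must be in (0, 1); got {v}")
        if self.cis_window <= 0:
            raise DataError("cis_window must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg
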