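"""End-to-end orchestration: simulate/load -> MR -> downstream -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .downstream import classify_beneficial, cms_enrichment
from .mr import MRRunResult, run_mr
from .simulate import SimConfig, make_cohort
from .types import Cohort

log = logging.getLogger(__name__)


def _obtain_cohorts(config: mio.PipelineConfig) -> Tuple[Cohort, Optional[Cohort]]:
    if config.inputs:
        disc = mio.load_cohort(**config.inputs["discovery"])
        val = (
            mio.load_cohort(**config.inputs["validation"])
            if "validation" in config.inputs else None
        )
        return disc, val
    sim = SimConfig(**{"seed": config.seed, **config.simulate})
    return make_cohort(sim)


def run_all(config: mio.PipelineConfig) -> dict:
    """Execute the configured stages and write a human-readable report.

    Returns a summary dict mirroring the written report: per-stage gene
    counts (genes in, eGenes, screened, causal, replicated) plus output
    paths.  Reruns with an identical config and seed regenerate every
    output identically.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    discovery, validation = _obtain_cohorts(config)
    summary["n_discovery"] = discovery.n
    summary["n_validation"] = validation.n if validation is not None else 0

    if not (config.run_eqtl and config.run_mr_stage):
        summary["stages"]["mr"] = "skipped"
        _write_report(summary, out)
        return summary

    mr_res: MRRunResult = run_mr(
        discovery,
        validation if config.run_twosample else None,
        cis_window=config.cis_window,
        n_perm=config.n_perm,
        alpha_egene=config.alpha_egene,
        alpha_screen=config.alpha_screen,
        alpha_causal=config.alpha_causal,
        p_nominal=config.p_nominal,
        r2_max=config.r2_max,
        pleiotropy_p=config.pleiotropy_p,
        k_clusters=config.k_clusters,
        corr_min=config.corr_min,
        seed=config.seed,
        run_twosample=config.run_twosample,
    )
    summary["stages"].update(mr_res.audit.get("stages", {}))
    summary["funnel"] = mr_res.audit.get("funnel", {})
    if not mr_res.results.empty:
        mr_res.results.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    mr_res.eqtl.pairs.to_csv(out / "eqtl_pairs.tsv", sep="\t", index=False)
    mr_res.eqtl.genes.to_csv(out / "eqtl_genes.tsv", sep="\t")

    if config.run_downstream and not mr_res.results.empty:
        causal = mr_res.results[mr_res.results["causal"]]
        enrich_rows = []
        expr = discovery.expression
        for _, row in causal.iterrows():
            direction = "harmful" if row["causal_effect"] > 0 else "protective"
            labels = classify_beneficial(expr, row["gene"], direction)
            enr = cms_enrichment(
                labels, discovery.clinical["cms"], gene=row["gene"], direction=direction
            )
            for subtype, frac in enr.fractions.iterrows():
                enrich_rows.append(
                    (row["gene"], row["arm"], direction, subtype,
                     frac["beneficial"], frac["non_beneficial"],
                     enr.enriched[subtype])
                )
        if enrich_rows:
            pd.DataFrame(
                enrich_rows,
                columns=["gene", "arm", "direction", "subtype",
                         "frac_beneficial", "frac_non_beneficial", "enriched"],
            ).to_csv(out / "cms_enrichment.tsv", sep="\t", index=False)
        summary["stages"]["enrichment_genes"] = int(causal.shape[0])
    elif not config.run_downstream:
        summary["stages"]["downstream"] = "skipped"

    _write_report(summary, out)
    return summary


def _write_report(summary: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    lines = ["analysis funnel", "==============="]
    for key, val in summary.get("stages", {}).items():
        lines.append(f"{key:>28}: {val}")
    for key, val in summary.get("funnel", {}).items():
        lines.append(f"{'funnel ' + key:>28}: {val}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
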