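import numpy as np
import pandas as pd
import pytest

from mrhaz.simulate import SimConfig, make_cohort
from mrhaz.types import ExpressionMatrix, GenotypeMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small linked discovery/validation pair shared across tests."""
    cfg = SimConfig(
        n_discovery=250,
        n_validation=120,
        n_genes=12,
        n_egenes=8,
        n_snps_per_gene=4,
        seed=7,
    )
    return make_cohort(cfg)


@pytest.fixture()
def toy_expression():
    """5 genes x 10 samples raw matrix with hand-checkable SDs and zeros.

    Under the default gene filter (SD >= 0.5, <= 30% zeros) the survivors
    are exactly g1 (30% zeros on the boundary) and g4.
    """
    rows = {
        "g0": [5.0] * 10,                                           # SD 0
        "g1": [0.0, 0.0, 0.0, 4.0, 9.0, 3.0, 7.0, 2.0, 6.0, 1.0],   # 3/10 zeros
        "g2": [0.0, 0.0, 0.0, 0.0, 8.0, 3.0, 5.0, 2.0, 7.0, 1.0],   # 4/10 zeros
        "g3": [2.0, 2.2, 2.4, 2.1, 2.3, 2.2, 2.1, 2.3, 2.2, 2.2],   # SD ~0.11
        "g4": [1.0, 9.0, 4.0, 7.0, 2.0, 8.0, 3.0, 6.0, 5.0, 10.0],
    }
    values = pd.DataFrame(rows, index=[f"S{i}" for i in range(10)]).T
    ann = pd.DataFrame(
        {"chrom": "chr1", "tss": np.arange(1, 6) * 1000}, index=values.index
    )
    return ExpressionMatrix(values, ann, scale="raw")


def make_genotypes(dosages: np.ndarray, positions=None, chrom="chr1"):
    """Wrap a samples x snps array into a GenotypeMatrix with annotation."""
    n, m = dosages.shape
    snps = [f"snp{j + 1}" for j in range(m)]
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "maf": np.clip(np.nanmean(dosages, axis=0) / 2, 1e-6, 0.5),
        },
        index=pd.Index(snps, name="snp_id"),
    )
    dos = pd.DataFrame(
        dosages.astype(float),
        index=pd.Index([f"S{i + 1}" for i in range(n)], name="sample_id"),
        columns=snps,
    )
    return GenotypeMatrix(dos, ann)
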