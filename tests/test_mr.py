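"""Instrument selection, prediction formulas, causal-test plumbing."""

import numpy as np
import pandas as pd
import pytest

from mrhaz.eqtl import EqtlTable
from mrhaz.mr import (
    causal_test,
    check_pleiotropy,
    cluster_genes,
    predict_expression_onesample,
    predict_expression_twosample,
    run_mr,
    screen_gene_os,
    select_instruments,
)
from mrhaz.simulate import (
    SimConfig,
    make_cohort,
    planted_causal_scenario,
    pleiotropy_scenario,
)
from mrhaz.types import DataError, ExpressionMatrix, GenotypeMatrix

from conftest import make_genotypes


def _table(rows):
    pairs = pd.DataFrame(rows, columns=["gene", "snp", "beta", "se", "nominal_p"])
    return EqtlTable(pairs=pairs)


def _expr_from(values: pd.DataFrame, chrom="chr1"):
    ann = pd.DataFrame(
        {"chrom": chrom, "tss": np.arange(1, len(values) + 1) * 1000},
        index=values.index,
    )
    return ExpressionMatrix(values, ann, scale="log2")


class TestClusterGenes:
    def test_separated_profiles_split_perfectly(self):
        rng = np.random.default_rng(40)
        a = rng.normal(0, 0.1, size=(5, 30))
        b = rng.normal(10, 0.1, size=(4, 30))
        values = pd.DataFrame(np.vstack([a, b]),
                              index=[f"g{i}" for i in range(9)],
                              columns=[f"S{j}" for j in range(30)])
        clusters = cluster_genes(_expr_from(values), values.index, k=2, seed=0)
        assert clusters.iloc[:5].nunique() == 1
        assert clusters.iloc[5:].nunique() == 1
        assert clusters.iloc[0] != clusters.iloc[-1]

    def test_same_seed_same_clustering(self, small_cohort):
        disc, _ = small_cohort
        genes = disc.truth["egenes"]
        c1 = cluster_genes(disc.expression, genes, k=3, seed=5)
        c2 = cluster_genes(disc.expression, genes, k=3, seed=5)
        pd.testing.assert_series_equal(c1, c2)

    def test_k_larger_than_genes_fails(self, small_cohort):
        disc, _ = small_cohort
        with pytest.raises(DataError):
            cluster_genes(disc.expression, disc.truth["egenes"][:3], k=4)


class TestSelectInstruments:
    def test_nominal_threshold_strict(self):
        rng = np.random.default_rng(41)
        dos = rng.binomial(2, 0.5, size=(100, 2)).astype(float)
        geno = make_genotypes(dos)
        table = _table([
            ("g", "snp1", 0.3, 0.1, 0.05),    # exactly .05 -> excluded
            ("g", "snp2", 0.3, 0.1, 0.049),   # kept
        ])
        instr = select_instruments(table, geno, "g")
        assert instr.snps == ["snp2"]

    def test_duplicate_snps_collapse_to_one_instrument(self):
        rng = np.random.default_rng(42)
        d = rng.binomial(2, 0.5, 200).astype(float)
        geno = make_genotypes(np.column_stack([d, d]))  # r^2 = 1
        table = _table([
            ("g", "snp1", 0.3, 0.1, 1e-4),
            ("g", "snp2", 0.29, 0.1, 5e-4),
        ])
        instr = select_instruments(table, geno, "g")
        assert instr.snps == ["snp1"]  # smaller nominal p wins

    def test_uncorrelated_candidates_all_kept(self):
        rng = np.random.default_rng(43)
        dos = rng.binomial(2, 0.5, size=(500, 4)).astype(float)
        geno = make_genotypes(dos)
        table = _table([
            ("g", f"snp{j}", 0.2, 0.1, 0.01 * j) for j in range(1, 5)
        ])
        instr = select_instruments(table, geno, "g")
        assert sorted(instr.snps) == ["snp1", "snp2", "snp3", "snp4"]

    def test_toy_ld_block_hand_clustering(self):
        # s1=s2 (r2=1), s3 nearly independent of both, s4=s1 with some flips
        rng = np.random.default_rng(44)
        s1 = rng.binomial(2, 0.5, 400).astype(float)
        s3 = rng.binomial(2, 0.5, 400).astype(float)
        s4 = s1.copy()
        flip = rng.random(400) < 0.1
        s4[flip] = rng.binomial(2, 0.5, flip.sum())
        dos = np.column_stack([s1, s1, s3, s4])
        geno = make_genotypes(dos)
        r2 = np.corrcoef(dos, rowvar=False) ** 2
        # hand expectation: {s1, s2, s4} form one high-LD cluster, {s3} alone
        assert r2[0, 1] > 0.99 and r2[0, 3] > 0.5 and r2[0, 2] < 0.1
        table = _table([
            ("g", "snp1", 0.30, 0.1, 1e-5),
            ("g", "snp2", 0.28, 0.1, 1e-4),
            ("g", "snp3", 0.20, 0.1, 1e-3),
            ("g", "snp4", 0.25, 0.1, 5e-4),
        ])
        instr = select_instruments(table, geno, "g")
        assert sorted(instr.snps) == ["snp1", "snp3"]

    def test_representatives_mutually_independent(self, small_cohort):
        disc, _ = small_cohort
        from mrhaz.eqtl import build_cis_pairs, nominal_scan
        from mrhaz.preprocess import build_covariates

        ann = disc.expression.gene_annotation
        pairs = build_cis_pairs(ann[ann["chrom"] != "chrY"],
                                disc.genotypes.snp_annotation)
        cov = build_covariates(disc.clinical, disc.abundances)
        table = nominal_scan(disc.expression, disc.genotypes, cov, pairs)
        for gene in disc.truth["egenes"]:
            instr = select_instruments(table, disc.genotypes, gene)
            if instr is None or instr.p < 2:
                continue
            r2 = np.corrcoef(
                disc.genotypes.dosages[instr.snps].to_numpy(), rowvar=False
            ) ** 2
            assert (r2[np.triu_indices_from(r2, k=1)] <= 0.1 + 1e-12).all()

    def test_no_candidates_returns_none(self):
        geno = make_genotypes(np.random.default_rng(0).binomial(2, 0.5, (50, 1)).astype(float))
        table = _table([("g", "snp1", 0.1, 0.1, 0.8)])
        assert select_instruments(table, geno, "g") is None


class TestPredictOneSample:
    def test_single_instrument_formula(self):
        rng = np.random.default_rng(45)
        d = rng.binomial(2, 0.4, 100).astype(float)
        geno = make_genotypes(d[:, None])
        from mrhaz.mr import InstrumentSet

        instr = InstrumentSet("g", ["snp1"], pd.Series({"snp1": 0.7}))
        pred = predict_expression_onesample(geno, instr)
        np.testing.assert_allclose(pred.values, 0.7 * (d - d.mean()))

    def test_zero_weights_fail_gate(self):
        rng = np.random.default_rng(46)
        d = rng.binomial(2, 0.4, 100).astype(float)
        geno = make_genotypes(d[:, None])
        from mrhaz.mr import InstrumentSet

        values = pd.DataFrame([d], index=["g"], columns=geno.sample_ids)
        expr = _expr_from(values)
        instr = InstrumentSet("g", ["snp1"], pd.Series({"snp1": 0.0}))
        pred = predict_expression_onesample(geno, instr, expr)
        assert not pred.prediction_ok and np.isnan(pred.corr)

    def test_missing_snp_listed(self):
        geno = make_genotypes(np.ones((10, 1)) * 1.0)
        from mrhaz.mr import InstrumentSet

        instr = InstrumentSet("g", ["absent"], pd.Series({"absent": 1.0}))
        with pytest.raises(DataError, match="absent"):
            predict_expression_onesample(geno, instr)

    def test_correlation_gate_near_sqrt_h2(self):
        """With h2 = 0.3 the in-sample correlation sits near sqrt(0.3) and
        the strict > 0.5 gate is applied as stated."""
        from mrhaz.eqtl import build_cis_pairs, nominal_scan
        from mrhaz.preprocess import build_covariates

        cfg = SimConfig(n_discovery=300, n_validation=0, n_genes=6, n_egenes=6,
                        n_snps_per_gene=5, n_causal_snps_per_egene=5,
                        ld_rho=0.25, seed=47)
        disc, _ = make_cohort(cfg)
        ann = disc.expression.gene_annotation
        pairs = build_cis_pairs(ann[ann["chrom"] != "chrY"],
                                disc.genotypes.snp_annotation)
        cov = build_covariates(disc.clinical, disc.abundances)
        table = nominal_scan(disc.expression, disc.genotypes, cov, pairs)
        corrs = []
        for gene in cfg.egene_ids():
            instr = select_instruments(table, disc.genotypes, gene)
            pred = predict_expression_onesample(disc.genotypes, instr,
                                                disc.expression)
            corrs.append(pred.corr)
            assert pred.prediction_ok == (pred.corr > 0.5)
        assert 0.4 <= np.mean(corrs) <= 0.7


class TestPredictTwoSample:
    @staticmethod
    def _instr(snps, weights=None):
        from mrhaz.mr import InstrumentSet

        w = pd.Series(1.0, index=snps) if weights is None else weights
        return InstrumentSet("g", list(snps), w)

    def test_in_sample_identity_with_ols_fit(self):
        rng = np.random.default_rng(48)
        Q = rng.binomial(2, 0.4, size=(120, 3)).astype(float)
        geno = make_genotypes(Q)
        g = 0.4 * Q[:, 0] - 0.2 * Q[:, 2] + rng.standard_normal(120)
        expr = _expr_from(pd.DataFrame([g], index=["g"], columns=geno.sample_ids))
        pred = predict_expression_twosample(geno, geno, expr,
                                            self._instr(geno.snp_ids))
        Qc = Q - Q.mean(axis=0)
        fitted = Qc @ np.linalg.lstsq(Qc, g - g.mean(), rcond=None)[0]
        np.testing.assert_allclose(pred.values, fitted, atol=1e-10)

    def test_single_instrument_is_simple_regression(self):
        rng = np.random.default_rng(49)
        d = rng.binomial(2, 0.3, 80).astype(float)
        d2 = rng.binomial(2, 0.3, 60).astype(float)
        g = 0.5 * d + rng.standard_normal(80)
        disc = make_genotypes(d[:, None])
        val = make_genotypes(d2[:, None])
        expr = _expr_from(pd.DataFrame([g], index=["g"], columns=disc.sample_ids))
        pred = predict_expression_twosample(val, disc, expr,
                                            self._instr(["snp1"]))
        dc = d - d.mean()
        slope = dc @ (g - g.mean()) / (dc @ dc)
        np.testing.assert_allclose(pred.values, slope * (d2 - d.mean()),
                                   atol=1e-12)

    def test_orthonormal_design_weights_are_projections(self):
        rng = np.random.default_rng(50)
        raw = rng.standard_normal((64, 3))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        g = rng.standard_normal(64)
        # wrap centered orthonormal columns as "dosages"
        geno = GenotypeMatrix(
            pd.DataFrame(Q, index=[f"S{i}" for i in range(64)],
                         columns=["snp1", "snp2", "snp3"]),
            pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3],
                          "ref": "A", "alt": "G", "maf": 0.3},
                         index=["snp1", "snp2", "snp3"]),
        )
        expr = _expr_from(pd.DataFrame([g], index=["g"], columns=geno.sample_ids))
        pred = predict_expression_twosample(geno, geno, expr,
                                            self._instr(geno.snp_ids))
        w = Q.T @ (g - g.mean())
        np.testing.assert_allclose(pred.values, Q @ w, atol=1e-10)

    def test_matches_lstsq_oracle_on_random_instances(self):
        rng = np.random.default_rng(51)
        for _ in range(10):
            p = rng.integers(1, 6)
            Q = rng.binomial(2, rng.uniform(0.1, 0.5), size=(100, p)).astype(float)
            Qv = rng.binomial(2, rng.uniform(0.1, 0.5), size=(60, p)).astype(float)
            g = rng.standard_normal(100)
            disc, val = make_genotypes(Q), make_genotypes(Qv)
            expr = _expr_from(pd.DataFrame([g], index=["g"],
                                           columns=disc.sample_ids))
            pred = predict_expression_twosample(val, disc, expr,
                                                self._instr(disc.snp_ids))
            Qc = Q - Q.mean(axis=0)
            w, *_ = np.linalg.lstsq(Qc, g - g.mean(), rcond=None)
            oracle = (Qv - Q.mean(axis=0)) @ w
            np.testing.assert_allclose(pred.values, oracle, rtol=1e-10,
                                       atol=1e-10)


class TestPleiotropy:
    def test_planted_direct_effect_excluded(self):
        from mrhaz.eqtl import build_cis_pairs, nominal_scan
        from mrhaz.preprocess import build_covariates, pca_expression
        from mrhaz.mr import select_instruments

        cfg = pleiotropy_scenario(seed=60)
        disc, _ = make_cohort(cfg)
        ann = disc.expression.gene_annotation
        pairs = build_cis_pairs(ann[ann["chrom"] != "chrY"],
                                disc.genotypes.snp_annotation)
        cov = build_covariates(disc.clinical, disc.abundances)
        table = nominal_scan(disc.expression, disc.genotypes, cov, pairs)
        instr = select_instruments(table, disc.genotypes, "G0001")
        assert "G0001_s1" in instr.snps  # the planted SNP is an eQTL
        pc1 = pca_expression(
            disc.expression.subset_genes(
                [g for g in disc.expression.gene_ids if not g.startswith("GY")]
            ), 1)
        gwas_cov = pd.DataFrame({
            "gender": disc.clinical["gender"].astype(float),
            "age": disc.clinical["age"],
            "all_ras": disc.clinical["all_ras"].astype(float),
            "PC1": pc1["PC1"],
        }, index=disc.clinical.index)
        cleaned = check_pleiotropy(instr, disc.clinical, gwas_cov,
                                   disc.genotypes)
        assert cleaned is None or "G0001_s1" not in cleaned.snps


class TestCausalTestAndRun:
    def test_empty_predictions_give_empty_result(self, small_cohort):
        disc, _ = small_cohort
        out = causal_test([], disc.clinical, disc.abundances, "bevacizumab")
        assert out.empty

    def test_stage_monotonicity_and_determinism(self):
        cfg = planted_causal_scenario(seed=70, n_per_arm=250, n_validation=200,
                                      n_egenes=12)
        disc, val = make_cohort(cfg)
        res1 = run_mr(disc, val, n_perm=300, seed=70)
        res2 = run_mr(disc, val, n_perm=300, seed=70)
        pd.testing.assert_frame_equal(res1.results, res2.results)
        r = res1.results
        assert (~r["instrumented"] | r["screened"]).all()
        assert (~r["prediction_ok"] | r["instrumented"]).all()
        assert (~r["causal"] | r["prediction_ok"]).all()
        f = res1.audit["funnel"]
        assert f["screened"] >= f["instrumented"] >= f["prediction_ok"] >= f["causal"]

    def test_screen_requires_enough_events(self, small_cohort):
        disc, _ = small_cohort
        clusters = cluster_genes(disc.expression, disc.truth["egenes"], k=2)
        starved = disc.clinical.copy()
        starved["event"] = 0
        starved.loc[starved.index[:5], "event"] = 1
        with pytest.raises(DataError, match="events"):
            screen_gene_os(disc.expression, starved, disc.abundances,
                           clusters, "bevacizumab")
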