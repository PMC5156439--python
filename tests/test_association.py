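import numpy as np
import pandas as pd
import pytest
from scipy import stats

import robustsig as rs
from robustsig.association import (fit_all_genes, fit_gene_linear,
                                   parameter_differential_expression,
                                   strain_signature)
from tests.conftest import planted_run

# frozen from an independent normal-equations + t-distribution oracle
# run before this module was written: x=(0,1,2,3,5), y=(1,2,3,4,5)
ORACLE_SLOPE = 0.8108108108108107
ORACLE_INTERCEPT = 1.2162162162162162
ORACLE_P = 0.0019012746601963686


class TestFitGeneLinear:
    def test_noiseless_line(self):
        x = np.linspace(-5, 0, 13)
        fit = fit_gene_linear(2 * x + 1, x)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.p_value < 1e-12
        assert fit.direction == "positive"

    def test_against_frozen_oracle(self):
        fit = fit_gene_linear([1, 2, 3, 4, 5], [0, 1, 2, 3, 5])
        assert fit.slope == pytest.approx(ORACLE_SLOPE, rel=1e-12)
        assert fit.intercept == pytest.approx(ORACLE_INTERCEPT, rel=1e-12)
        assert fit.p_value == pytest.approx(ORACLE_P, rel=1e-9)

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=13)
        expr = pd.DataFrame(rng.normal(size=(10000, 13)))
        fits = fit_all_genes(expr, x)
        ks = stats.kstest(fits["p_value"], "uniform").statistic
        assert ks < 0.02

    def test_affine_invariance_of_p(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=13)
        y = rng.normal(size=13)
        base = fit_gene_linear(y, x)
        scaled = fit_gene_linear(3.0 * y + 7.0, x)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)
        assert scaled.slope == pytest.approx(3.0 * base.slope, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_gene_linear([1, 2, 3], [1, 2, 3])        # too short
        with pytest.raises(ValueError):
            fit_gene_linear([1, 2, 3, 4], [1, 1, 1, 1])  # zero variance
        with pytest.raises(ValueError):
            fit_gene_linear([1, 2, 3, 4], [1, 2, 3])     # length mismatch

    def test_matrix_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=13)
        expr = pd.DataFrame(rng.normal(size=(20, 13)),
                            index=[f"g{i}" for i in range(20)])
        fits = fit_all_genes(expr, x)
        for g in ("g0", "g7", "g19"):
            single = fit_gene_linear(expr.loc[g], x, gene_id=g)
            assert fits.loc[g, "slope"] == pytest.approx(single.slope)
            assert fits.loc[g, "p_value"] == pytest.approx(single.p_value)


def _results(genes, ps, slopes):
    return pd.DataFrame({"p_value": ps, "slope": slopes},
                        index=pd.Index(genes, name="gene_id"))


class TestStrainSignature:
    def test_fails_one_timepoint_excluded(self):
        r1 = _results(["g1"], [0.04], [1.0])
        r2 = _results(["g1"], [0.06], [1.0])
        assert len(strain_signature(r1, r2)) == 0

    def test_product_flag(self):
        r1 = _results(["g1"], [0.001], [1.0])
        r2 = _results(["g1"], [0.01], [2.0])
        sig = strain_signature(r1, r2)
        assert len(sig) == 1
        row = sig.iloc[0]
        assert row.p_product == pytest.approx(1e-5)
        assert bool(row.most_significant)
        assert row.avg_slope == pytest.approx(1.5)
        assert row.slope == pytest.approx(1.5)
        assert row.direction == "positive"

    def test_sign_conflict_excluded(self):
        r1 = _results(["g1"], [0.001], [1.0])
        r2 = _results(["g1"], [0.001], [-1.0])
        assert len(strain_signature(r1, r2)) == 0

    def test_ranked_ascending(self):
        r1 = _results(["a", "b"], [0.01, 0.001], [1, 1])
        r2 = _results(["a", "b"], [0.01, 0.001], [1, 1])
        sig = strain_signature(r1, r2)
        assert list(sig.gene_id) == ["b", "a"]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        p1, p2 = rng.uniform(size=200), rng.uniform(size=200)
        s = rng.normal(size=200)
        r1, r2 = _results(genes, p1, s), _results(genes, p2, s)
        small = set(strain_signature(r1, r2, alpha=0.05).gene_id)
        large = set(strain_signature(r1, r2, alpha=0.2).gene_id)
        assert small <= large

    def test_subset_of_both_alpha_sets(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        r1 = _results(genes, rng.uniform(size=100), rng.normal(size=100))
        r2 = _results(genes, rng.uniform(size=100), rng.normal(size=100))
        sig = strain_signature(r1, r2, alpha=0.1)
        assert set(sig.gene_id) <= set(r1.index[r1.p_value < 0.1])
        assert set(sig.gene_id) <= set(r2.index[r2.p_value < 0.1])

    def test_threshold_validation(self):
        r = _results(["g1"], [0.01], [1.0])
        with pytest.raises(ValueError):
            strain_signature(r, r, alpha=0.0)
        with pytest.raises(ValueError):
            strain_signature(r, r, product_threshold=2.0)

    def test_different_universe_rejected(self):
        r1 = _results(["g1"], [0.01], [1.0])
        r2 = _results(["g2"], [0.01], [1.0])
        with pytest.raises(ValueError):
            strain_signature(r1, r2)


class TestPlantedRecovery:
    def test_recovery_and_false_positives(self):
        # smaller version of the 50-seed acceptance experiment
        recs, fps = [], []
        for seed in range(10):
            sig, planted = planted_run(seed)
            flagged = set(sig.loc[sig.most_significant, "gene_id"])
            recs.append(100 * len(flagged & planted) / len(planted))
            fps.append(len(flagged - planted))
        assert np.median(recs) >= 80
        assert np.median(fps) <= 1

    def test_null_flag_count(self):
        counts = [planted_run(seed, n_planted=0)[0].most_significant.sum()
                  for seed in range(10)]
        assert np.median(counts) <= 1


class TestParameterDifferentialExpression:
    def test_planted_oxygen_effect(self, design):
        rng = np.random.default_rng(0)
        oxy = np.array([c.oxygen == "high" for c in design], dtype=float)
        n_genes = 400
        expr = rng.normal(size=(n_genes, 13))
        expr[:50] += 3.0 * oxy  # strong oxygen effect in the first 50 genes
        frame = pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)],
                             columns=[c.fermentation_id for c in design])
        res = parameter_differential_expression(frame, design)
        planted = {f"g{i}" for i in range(50)}
        assert len(planted & res.gene_sets["oxygen"]) >= 45
        for other in ("salt", "pH", "temperature"):
            assert len(res.gene_sets[other]) < 0.15 * n_genes

    def test_alpha_one_degenerate(self, design):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(30, 13)),
                             columns=[c.fermentation_id for c in design])
        res = parameter_differential_expression(frame, design, alpha=1.0)
        for s in res.gene_sets.values():
            assert len(s) == 30
        assert (res.overlap_pct.to_numpy() == 100.0).all()

    def test_identical_parameters_full_overlap(self, design):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(size=(50, 13)),
                             columns=[c.fermentation_id for c in design])
        res = parameter_differential_expression(frame, design)
        # diagonal entries compare a parameter with itself
        for p in res.overlap_pct.index:
            if len(res.gene_sets[p]):
                assert res.overlap_pct.loc[p, p] == 100.0

    def test_single_level_rejected(self, design):
        import dataclasses
        flat = [dataclasses.replace(c, salt=0) for c in design]
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(25, 13)),
                             columns=[c.fermentation_id for c in design])
        with pytest.raises(ValueError, match="salt"):
            parameter_differential_expression(frame, flat)
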