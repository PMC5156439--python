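import dataclasses

import numpy as np
import pandas as pd
import pytest

import robustsig as rs
from robustsig import phenotype
from robustsig.simulate import DEFAULT_TIMEPOINTS, LoopDesign, gene_ids


class TestGenerateDesign:
    def test_record_1(self, design):
        c = design[0]
        assert (c.salt, c.initial_ph, c.temperature, c.oxygen, c.day) == \
            (0, 6.0, 27, "high", 1)

    def test_record_13(self, design):
        c = design[12]
        assert (c.salt, c.initial_ph, c.temperature, c.oxygen, c.day) == \
            (100, 6.5, 30, "low", 2)

    def test_cardinality_and_ids(self, design):
        assert len(design) == 13
        ids = [c.fermentation_id for c in design]
        assert ids == list(range(1, 14))

    def test_fermentation_13_replicates_6(self, design):
        c6, c13 = design[5], design[12]
        assert (c6.salt, c6.initial_ph, c6.temperature, c6.oxygen) == \
            (c13.salt, c13.initial_ph, c13.temperature, c13.oxygen)
        assert (c6.day, c13.day) == (1, 2)

    def test_days(self, design):
        assert [c.day for c in design] == [1] * 6 + [2] * 7


class TestGeneratePhenotypes:
    def test_degenerate_profile_all_equal(self, design):
        rob, _ = rs.generate_phenotypes(
            design, {"heat": {}, "oxidative": {}}, dynamic_range_target=None,
            seed=0, noise_sd=0.0)
        for (_, _), grp in rob.groupby(["stress", "timepoint_min"]):
            surv = grp["true_survival_pct"]
            assert phenotype.dynamic_range(surv) == pytest.approx(0.0, abs=1e-12)

    def test_negative_target_rejected(self, design):
        with pytest.raises(ValueError):
            rs.generate_phenotypes(design, dynamic_range_target=-1.0)

    def test_single_timepoint_rejected(self, design):
        with pytest.raises(ValueError):
            rs.generate_phenotypes(design, timepoints={"heat": (10,)})

    def test_oxygen_effect_power(self, design):
        # planted high-vs-low oxygen effect of 1.8 log10 with sd 0.3 noise
        # must be detected by a Welch t-test in at least 95 of 100 seeds
        oxy = [c.oxygen for c in design]
        hits = 0
        for seed in range(100):
            rob, _ = rs.generate_phenotypes(
                design, {"heat": {"oxygen": 1.8}}, dynamic_range_target=None,
                timepoints={"heat": (10, 30)}, seed=seed, noise_sd=0.3)
            r = rob[(rob.stress == "heat") & (rob.timepoint_min == 10)]
            res = phenotype.parameter_effect_ttest(
                r["true_robustness"].to_numpy(), oxy)
            hits += res.p_value < 0.05
        assert hits >= 95

    def test_realized_dynamic_range_near_target(self, design):
        rob, _ = rs.generate_phenotypes(design, dynamic_range_target=5.0,
                                        seed=3, noise_sd=0.3)
        r = rob[(rob.stress == "heat") & (rob.timepoint_min == 10)]
        realized = phenotype.dynamic_range(r["true_survival_pct"])
        assert realized == pytest.approx(5.0, abs=1.0)

    def test_survival_matches_robustness(self, design):
        rob, _ = rs.generate_phenotypes(design, seed=5)
        np.testing.assert_allclose(
            rob["true_robustness"],
            np.log10(rob["true_survival_pct"] / 100.0), atol=1e-9)

    def test_seed_determinism(self, design):
        a = rs.generate_phenotypes(design, seed=11)
        b = rs.generate_phenotypes(design, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_poisson_cfu_mean_matches_truth(self, design):
        # duplicate-derived survival is unbiased for the true survival
        first = design[:1]
        est, true = [], []
        for seed in range(1000):
            rob, cfu = rs.generate_phenotypes(first, seed=seed, noise_sd=0.0,
                                              n0=1e6)
            row = rob.iloc[0]
            g = cfu[(cfu.stress == row.stress)
                    & (cfu.timepoint_min == row.timepoint_min)]
            est.append(phenotype.compute_survival(g.n0, g.nt).survival_pct)
            true.append(row.true_survival_pct)
        assert np.mean(est) / np.mean(true) == pytest.approx(1.0, abs=0.05)


class TestGenerateExpression:
    def test_noiseless_recovery(self):
        r = pd.Series(np.linspace(-5, -0.5, 13), index=range(1, 14),
                      name="heat")
        truth = rs.SyntheticTruth(
            planted_genes={"heat": frozenset({"g0001"})},
            slopes={"heat": {"g0001": 2.0}}, noise_sd=1e-9, seed=0,
            n_genes=10)
        expr, _ = rs.generate_expression(r, 10, truth)
        fit = rs.fit_gene_linear(expr.loc["g0001"], r)
        assert fit.slope == pytest.approx(2.0, abs=1e-6)
        assert fit.p_value < 1e-10

    def test_too_few_genes_rejected(self):
        r = pd.Series(np.arange(13, dtype=float), index=range(1, 14), name="s")
        truth = rs.make_truth(50, {"s": 20}, seed=1)
        with pytest.raises(ValueError):
            rs.generate_expression(r, 10, truth)

    def test_determinism(self):
        r = pd.Series(np.linspace(-4, 0, 13), index=range(1, 14), name="heat")
        truth = rs.make_truth(100, {"heat": 5}, seed=7)
        a, _ = rs.generate_expression(r, 100, truth)
        b, _ = rs.generate_expression(r, 100, truth)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_slope_planted_rejected(self):
        with pytest.raises(ValueError):
            rs.SyntheticTruth(planted_genes={"heat": frozenset({"g0001"})},
                              slopes={"heat": {"g0001": 0.0}}, noise_sd=0.5,
                              seed=0, n_genes=10)


class TestLoopDesign:
    def test_default_two_loops_connected(self, loop_design):
        assert loop_design.is_connected()
        assert loop_design.samples == list(range(1, 14))
        assert len(loop_design.hybridizations) == 14  # 6 + 7 + bridge

    def test_dye_balance(self, loop_design):
        counts = loop_design.dye_counts()
        # within-loop samples are balanced; the bridge adds one extra
        # appearance for samples 6 (cy3) and 13 (cy5)
        assert (counts.loc[1:5, "cy5"] == 1).all()
        assert (counts.loc[1:5, "cy3"] == 1).all()
        assert counts.loc[6, "cy3"] == 2
        assert counts.loc[13, "cy5"] == 2

    def test_disconnected_graph_detected(self):
        d = LoopDesign(hybridizations=(("A1", 1, 2), ("A2", 3, 4)))
        assert not d.is_connected()

    def test_frame_round_trip(self, loop_design):
        again = LoopDesign.from_frame(loop_design.frame())
        assert again.hybridizations == loop_design.hybridizations


class TestGenerateProbeIntensities:
    @pytest.fixture()
    def expr(self):
        r = pd.Series(np.linspace(-4, 0, 13), index=range(1, 14), name="heat")
        truth = rs.make_truth(30, {"heat": 5}, seed=3)
        return rs.generate_expression(r, 30, truth)[0]

    def test_identity_channel(self, expr, loop_design):
        inten, _ = rs.generate_probe_intensities(expr, 1, loop_design,
                                                 dye_bias=None, seed=0,
                                                 noise_sd=0.0)
        for array_id, s5, s3 in loop_design.hybridizations:
            grp = inten[inten.array_id == array_id].set_index("probe_id")
            m = np.log2(grp["cy5"] / grp["cy3"])
            true_m = (expr[s5] - expr[s3]).to_numpy()
            np.testing.assert_allclose(m.to_numpy(), true_m, atol=1e-9)

    def test_probe_map_cardinality(self, expr, loop_design):
        _, pmap = rs.generate_probe_intensities(expr, 3, loop_design, seed=0)
        assert len(pmap) == 3 * len(expr)
        assert (pmap.groupby("orf_id").size() == 3).all()

    def test_unknown_fermentation_rejected(self, expr):
        bad = LoopDesign(hybridizations=(("A1", 1, 99),))
        with pytest.raises(ValueError):
            rs.generate_probe_intensities(expr, 1, bad)

    def test_probes_per_gene_validated(self, expr, loop_design):
        with pytest.raises(ValueError):
            rs.generate_probe_intensities(expr, 0, loop_design)


class TestGenerateOgMap:
    def test_fully_shared(self):
        og = rs.generate_og_map(["a", "b", "c", "d"], 50, 1.0, seed=0)
        assert len(og) == 50
        assert og[["a", "b", "c", "d"]].notna().all().all()

    def test_nothing_shared(self):
        og = rs.generate_og_map(["a", "b"], 50, 0.0, seed=0)
        assert (og[["a", "b"]].notna().sum(axis=1) < 2).all()

    def test_determinism(self):
        a = rs.generate_og_map(["a", "b", "c"], 40, 0.5, seed=9)
        b = rs.generate_og_map(["a", "b", "c"], 40, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_validation(self):
        with pytest.raises(ValueError):
            rs.generate_og_map(["only"], 10, 1.0)
        with pytest.raises(ValueError):
            rs.generate_og_map(["a", "b"], 10, 1.5)
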