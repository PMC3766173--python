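import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osrr import (
    CovariateTable,
    ExpressionMatrix,
    NetworkModel,
    NetworkPrediction,
    adjust_pvalues,
    center_genes,
    cosgrove_residual,
    fit_de_gene,
    fit_interaction_gene,
    run_de_analysis,
    summarize_counts,
)


def two_group_cov(n_per=5):
    return CovariateTable(condition=np.array([0] * n_per + [1] * n_per))


class TestFitDeGene:
    def test_naive_equals_pooled_t_test(self, rng):
        cov = two_group_cov(6)
        for _ in range(5):
            y = rng.standard_normal(12)
            res = fit_de_gene(y, None, cov)
            t_p = stats.ttest_ind(y[6:], y[:6], equal_var=True).pvalue
            assert res.p_delta == pytest.approx(t_p, abs=1e-12)
            assert res.model_tag == "naive"

    def test_constant_predictor_falls_back_to_naive(self, rng):
        cov = two_group_cov(5)
        y = rng.standard_normal(10)
        res = fit_de_gene(y, np.full(10, 3.0), cov)
        naive = fit_de_gene(y, None, cov)
        assert res.degenerate and res.model_tag == "naive"
        assert res.p_delta == pytest.approx(naive.p_delta, abs=1e-15)

    def test_no_signal_gives_zero_delta(self, rng):
        # identical group means by construction, noise only in the predictor
        y = np.tile(np.arange(5.0), 2)
        yhat = rng.standard_normal(10)
        yhat -= np.array([yhat[:5].mean()] * 5 + [yhat[5:].mean()] * 5)  # balanced
        res = fit_de_gene(y, yhat, two_group_cov(5))
        assert res.delta_hat == pytest.approx(0.0, abs=1e-10)

    def test_generative_recovery(self):
        # simulate straight from the model: y = nu*yhat + delta*x + eps
        deltas = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 200
            x = np.array([0] * (n // 2) + [1] * (n // 2))
            yhat = rng.standard_normal(n)
            y = 0.8 * yhat + 1.5 * x + rng.standard_normal(n)
            res = fit_de_gene(y, yhat, CovariateTable(condition=x))
            assert abs(res.delta_hat - 1.5) < 4.5 * res.se_delta
            deltas.append(res.delta_hat)
        assert np.mean(deltas) == pytest.approx(1.5, abs=0.05)

    def test_single_level_condition_rejected(self, rng):
        with pytest.raises(ValueError, match="both levels"):
            fit_de_gene(
                rng.standard_normal(6),
                None,
                CovariateTable(condition=np.zeros(6, dtype=int)),
            )

    def test_fixed_pairing_absorbs_pair_shifts(self, rng):
        # a huge pair-specific shift should not inflate the condition test
        cov = CovariateTable(
            condition=np.array([0, 1] * 6),
            pair_id=[f"p{i // 2}" for i in range(12)],
        )
        shifts = np.repeat(rng.normal(0, 50, 6), 2)
        y = shifts + rng.standard_normal(12)
        res_fixed = fit_de_gene(y, None, cov, pairing="fixed")
        res_none = fit_de_gene(y, None, cov, pairing="none")
        assert res_fixed.se_delta < res_none.se_delta

    def test_random_pairing_runs_and_detects_effect(self, rng):
        cov = CovariateTable(
            condition=np.array([0, 1] * 8),
            pair_id=[f"p{i // 2}" for i in range(16)],
        )
        shifts = np.repeat(rng.normal(0, 5, 8), 2)
        y = shifts + 2.0 * cov.condition + 0.3 * rng.standard_normal(16)
        res = fit_de_gene(y, None, cov, pairing="random")
        assert res.p_delta < 0.01
        assert res.delta_hat == pytest.approx(2.0, abs=0.5)

    def test_random_pairing_zero_variance_matches_ols(self, rng):
        # no pair effect at all: the variance component hits the zero
        # boundary and the fit falls back to plain least squares
        cov = CovariateTable(
            condition=np.array([0, 1] * 6),
            pair_id=[f"p{i // 2}" for i in range(12)],
        )
        y = rng.standard_normal(12)
        res_rand = fit_de_gene(y, None, cov, pairing="random")
        res_ols = fit_de_gene(y, None, cov, pairing="none")
        assert res_rand.p_delta == pytest.approx(res_ols.p_delta, abs=1e-8)

    def test_pairing_requires_pair_id(self, rng):
        with pytest.raises(ValueError, match="pair_id"):
            fit_de_gene(rng.standard_normal(10), None, two_group_cov(5), pairing="random")


class TestFitInteractionGene:
    def test_type1_error_calibrated_under_null(self):
        # gamma = 0 truth: same nu in both groups
        rng = np.random.default_rng(99)
        n, n_genes = 40, 4000
        x = np.array([0] * 20 + [1] * 20)
        cov = CovariateTable(condition=x)
        p_gamma = []
        for _ in range(n_genes):
            yhat = rng.standard_normal(n)
            y = 1.0 * yhat + 0.5 * x + rng.standard_normal(n)
            p_gamma.append(fit_interaction_gene(y, yhat, cov).p_gamma)
        p_gamma = np.asarray(p_gamma)
        lo, hi = stats.binom.interval(0.99, n_genes, 0.05)
        assert lo <= (p_gamma < 0.05).sum() <= hi
        assert stats.kstest(p_gamma, "uniform").pvalue > 0.01

    def test_gamma_recovery(self):
        gammas = []
        x = np.array([0] * 20 + [1] * 20)
        cov = CovariateTable(condition=x)
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            yhat = rng.standard_normal(40)
            y = 1.0 * yhat - 0.5 * yhat * x + rng.standard_normal(40) * 0.5
            gammas.append(fit_interaction_gene(y, yhat, cov).gamma_hat)
        assert np.mean(gammas) == pytest.approx(-0.5, abs=0.1)

    def test_collinear_interaction_flagged_not_crashed(self, rng):
        # predictor constant within cases: interaction column collinear
        x = np.array([0] * 5 + [1] * 5)
        yhat = np.concatenate([rng.standard_normal(5), np.full(5, 2.0)])
        y = rng.standard_normal(10)
        res = fit_interaction_gene(y, yhat, CovariateTable(condition=x))
        assert res.degenerate
        assert np.isfinite(res.delta_hat)


class TestCosgroveResidual:
    def test_zero_network_returns_data(self, small_centered):
        model = NetworkModel(np.zeros((8, 8)), lam=1.0, gene_ids=small_centered.gene_ids)
        effects = cosgrove_residual(small_centered, model)
        for g, eff in enumerate(effects):
            np.testing.assert_array_equal(eff.residual, small_centered.values[g])

    def test_fixed_point_construction_gives_zero_residual(self):
        # build y as an eigenvector of B with eigenvalue 1 so y = By exactly
        B = np.array(
            [
                [0.0, 0.5, 0.5, 0.0],
                [0.5, 0.0, 0.0, 0.5],
                [0.5, 0.0, 0.0, 0.5],
                [0.0, 0.5, 0.5, 0.0],
            ]
        )
        w, v = np.linalg.eig(B)
        vec = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        y = np.column_stack([vec, -vec, 2 * vec])
        y = y - y.mean(axis=1, keepdims=True)  # spans of vec stay eigen
        m = ExpressionMatrix(y, list("abcd"), ["s1", "s2", "s3"], centered=True)
        model = NetworkModel(B, lam=1.0, gene_ids=list("abcd"))
        for eff in cosgrove_residual(m, model):
            np.testing.assert_allclose(eff.residual, 0.0, atol=1e-10)

    def test_matches_loop_oracle_with_conditions(self, rng):
        vals = rng.standard_normal((6, 5))
        vals -= vals.mean(axis=1, keepdims=True)
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(6)], [f"s{j}" for j in range(5)],
                             centered=True)
        coef = rng.standard_normal((6, 6))
        np.fill_diagonal(coef, 0.0)
        model = NetworkModel(coef, lam=1.0, gene_ids=m.gene_ids)
        cov = CovariateTable(condition=np.array([0, 0, 1, 1, 1]))
        effects = cosgrove_residual(m, model, cov)
        for g, eff in enumerate(effects):
            expected = np.array(
                [vals[g, n] - sum(coef[g, h] * vals[h, n] for h in range(6))
                 for n in range(5)]
            )
            np.testing.assert_allclose(eff.residual, expected, atol=1e-12)
            assert eff.phi_hat[0] == pytest.approx(expected[:2].mean(), abs=1e-12)
            assert eff.phi_hat[1] == pytest.approx(expected[2:].mean(), abs=1e-12)


class TestAdjustPvalues:
    def test_hand_computed_bh(self):
        q = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones_and_singleton(self):
        np.testing.assert_array_equal(adjust_pvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert adjust_pvalues([0.3])[0] == pytest.approx(0.3)

    def test_bh_q_at_least_p_and_monotone(self, rng):
        p = rng.random(100)
        q = adjust_pvalues(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_storey_scales_by_pi0(self, rng):
        p = np.concatenate([rng.random(80), rng.random(20) * 1e-4])
        q_bh, q_st = adjust_pvalues(p, "bh"), adjust_pvalues(p, "storey")
        assert np.all(q_st <= q_bh + 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_pvalues([0.5, 1.5])


class TestRunDeAnalysis:
    @pytest.fixture
    def toy(self, rng):
        n_genes, n = 10, 12
        vals = rng.standard_normal((n_genes, n))
        expt = ExpressionMatrix(
            vals, [f"g{i:02d}" for i in range(n_genes)], [f"s{j}" for j in range(n)]
        )
        pred = NetworkPrediction(
            rng.standard_normal((n_genes, n)), list(expt.gene_ids), list(expt.sample_ids)
        )
        cov = CovariateTable(condition=np.array([0] * 6 + [1] * 6))
        return expt, pred, cov

    def test_row_count_and_composition(self, toy):
        expt, pred, cov = toy
        table = run_de_analysis(expt, pred, cov)
        assert len(table) == expt.n_genes
        for g, gene in enumerate(expt.gene_ids):
            single = fit_de_gene(expt.values[g], pred.values[g], cov, gene_id=gene)
            row = table.iloc[g]
            assert row["p_delta"] == pytest.approx(single.p_delta, abs=1e-15)
            assert row["delta_hat"] == pytest.approx(single.delta_hat, abs=1e-15)

    def test_prediction_scale_invariance(self, toy):
        # delta and its p-value are invariant to rescaling the network
        # predictor; gamma rescales by 1/c
        expt, pred, cov = toy
        base = run_de_analysis(expt, pred, cov, with_interaction=True)
        for c in (0.01, 100.0):
            scaled_pred = NetworkPrediction(
                c * pred.values, list(pred.gene_ids), list(pred.sample_ids)
            )
            scaled = run_de_analysis(expt, scaled_pred, cov, with_interaction=True)
            np.testing.assert_allclose(
                scaled["delta_hat"], base["delta_hat"], atol=1e-10
            )
            np.testing.assert_allclose(scaled["p_delta"], base["p_delta"], atol=1e-10)
            np.testing.assert_allclose(
                scaled["gamma_hat"] * c, base["gamma_hat"], atol=1e-8
            )
            np.testing.assert_allclose(scaled["p_gamma"], base["p_gamma"], atol=1e-10)

    def test_null_batch_property(self):
        # with no simulated effects, tiny p-values are rare across seeds
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expt = ExpressionMatrix(
                rng.standard_normal((10, 12)),
                [f"g{i}" for i in range(10)],
                [f"s{j}" for j in range(12)],
            )
            cov = CovariateTable(condition=np.array([0] * 6 + [1] * 6))
            table = run_de_analysis(expt, None, cov)
            hits += int((table["p_delta"] < 1e-4).any())
        assert hits <= 1

    def test_mismatched_prediction_rejected(self, toy, rng):
        expt, pred, cov = toy
        bad = NetworkPrediction(
            pred.values, [f"x{i}" for i in range(10)], list(pred.sample_ids)
        )
        with pytest.raises(ValueError, match="gene ids"):
            run_de_analysis(expt, bad, cov)

    def test_summary_counts_layout(self, toy):
        expt, pred, cov = toy
        table = run_de_analysis(expt, pred, cov)
        counts = summarize_counts(table)
        assert set(counts) == {"Up", "Down"}
        assert set(counts["Up"]) == {"0.05", "0.01", "0.001", "0.0001"}
        total_at_05 = counts["Up"]["0.05"] + counts["Down"]["0.05"]
        assert total_at_05 == int((table["p_delta"] < 0.05).sum())
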