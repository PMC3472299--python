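"""Group-means fit, variance prior, moderated t, BH FDR, DE calls."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betainc

from uprflow import (
    ExpressionMatrix,
    PriorEstimate,
    bh_adjust,
    classify_de,
    consistent_de_sets,
    default_design,
    estimate_prior,
    fit_group_means,
    generate_expression_matrix,
    moderated_t,
    run_de,
    signed_linear_fold_change,
)
from uprflow.de import D0_INFINITE_CAP


def two_group_expr():
    arrays = [f"a{i}" for i in range(6)]
    design = pd.DataFrame(
        {
            "array_id": arrays,
            "condition": ["WT"] * 3 + ["CA1"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )
    expr = ExpressionMatrix(
        pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g1"], columns=arrays)
    )
    return expr, design


class TestFitGroupMeans:
    def test_hand_computed_two_group_fit(self):
        expr, design = two_group_expr()
        fit = fit_group_means(expr, design)
        assert fit.group_means.loc["g1", "WT"] == pytest.approx(2.0)
        assert fit.group_means.loc["g1", "CA1"] == pytest.approx(5.0)
        assert fit.residual_df == 4
        assert fit.residual_variance["g1"] == pytest.approx(1.0)

    def test_identical_replicates_give_zero_variance(self, design):
        values = np.tile(np.arange(4.0, 9.0)[:, None], (1, 12))
        expr = ExpressionMatrix(
            pd.DataFrame(values, columns=design["array_id"].tolist())
        )
        fit = fit_group_means(expr, design)
        assert np.allclose(fit.residual_variance, 0.0)
        assert fit.residual_df == 8

    def test_array_permutation_invariance(self, small_expression, design):
        expr, _ = small_expression
        fit1 = fit_group_means(expr, design)
        perm = np.random.default_rng(0).permutation(12)
        shuffled = ExpressionMatrix(expr.values.iloc[:, perm])
        fit2 = fit_group_means(shuffled, design)
        assert np.allclose(
            fit1.group_means.to_numpy(), fit2.group_means[fit1.group_means.columns].to_numpy()
        )
        assert np.allclose(fit1.residual_variance, fit2.residual_variance)

    def test_missing_array_rejected(self, small_expression, design):
        expr, _ = small_expression
        with pytest.raises(ValueError):
            fit_group_means(expr, design.iloc[:-1])


class TestEstimatePrior:
    def test_equal_variances_give_infinite_d0(self):
        s = np.full(100, 0.25)
        prior = estimate_prior(s, d=8)
        assert prior.is_infinite
        assert prior.s0_sq == pytest.approx(0.25, rel=1e-12)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(11)
        d0_true, s0_true, d, n = 4.0, 0.05, 8, 20000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(50), d=8)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.ones(5), d=8)


class TestModeratedT:
    def fit_for(self, delta, s_sq, n=3):
        arrays = [f"a{i}" for i in range(2 * n)]
        design = pd.DataFrame(
            {
                "array_id": arrays,
                "condition": ["CA1"] * n + ["WT"] * n,
                "replicate": list(range(1, n + 1)) * 2,
            }
        )
        from uprflow.de import LinearFit

        return LinearFit(
            group_means=pd.DataFrame({"CA1": [delta], "WT": [0.0]}, index=["g"]),
            residual_variance=pd.Series([s_sq], index=["g"]),
            residual_df=8,
            n_per_condition={"CA1": n, "WT": n},
        )

    def test_closed_form_arithmetic_and_cdf_oracle(self):
        fit = self.fit_for(delta=1.0, s_sq=0.5)
        prior = PriorEstimate(d0=4.0, s0_sq=0.25)
        res = moderated_t(fit, prior, ("CA1", "WT"))
        s_tilde = (4 * 0.25 + 8 * 0.5) / 12
        assert s_tilde == pytest.approx(0.41667, abs=5e-6)
        t_expected = 1.0 / math.sqrt(s_tilde * (2 / 3))
        assert t_expected == pytest.approx(1.897, abs=5e-4)
        assert res.loc["g", "t_mod"] == pytest.approx(t_expected, rel=1e-12)
        # p from t_12 via the regularized incomplete beta closed form
        df = 12.0
        p_oracle = betainc(df / 2, 0.5, df / (df + t_expected**2))
        assert res.loc["g", "p_value"] == pytest.approx(p_oracle, rel=1e-10)

    def test_no_moderation_limit_equals_pooled_t(self):
        fit = self.fit_for(delta=0.8, s_sq=0.3)
        res = moderated_t(fit, PriorEstimate(d0=0.0, s0_sq=1.0), ("CA1", "WT"))
        t_pooled = 0.8 / math.sqrt(0.3 * (2 / 3))
        assert res.loc["g", "t_mod"] == pytest.approx(t_pooled, rel=1e-12)
        assert res.loc["g", "p_value"] == pytest.approx(
            2 * stats.t.sf(t_pooled, df=8), rel=1e-12
        )

    def test_zero_difference_gives_p_one(self):
        fit = self.fit_for(delta=0.0, s_sq=0.5)
        res = moderated_t(fit, PriorEstimate(d0=4.0, s0_sq=0.25), ("CA1", "WT"))
        assert res.loc["g", "t_mod"] == 0.0
        assert res.loc["g", "p_value"] == pytest.approx(1.0)

    def test_infinite_prior_uses_prior_variance_and_normal(self):
        fit = self.fit_for(delta=1.0, s_sq=0.5)
        prior = PriorEstimate(d0=D0_INFINITE_CAP, s0_sq=0.25)
        res = moderated_t(fit, prior, ("CA1", "WT"))
        t_expected = 1.0 / math.sqrt(0.25 * (2 / 3))
        assert res.loc["g", "t_mod"] == pytest.approx(t_expected)
        assert res.loc["g", "p_value"] == pytest.approx(
            2 * stats.norm.sf(t_expected), rel=1e-12
        )

    def test_degenerate_variance_flagged_not_zero_p(self):
        fit = self.fit_for(delta=1.0, s_sq=0.0)
        res = moderated_t(fit, PriorEstimate(d0=0.0, s0_sq=1.0), ("CA1", "WT"))
        assert bool(res.loc["g", "degenerate"])
        assert np.isnan(res.loc["g", "p_value"])

    def test_moderation_shrinks_between_sample_and_prior(self):
        rng = np.random.default_rng(2)
        prior = PriorEstimate(d0=4.0, s0_sq=0.1)
        for s_sq in rng.uniform(0.01, 1.0, size=20):
            post = (prior.d0 * prior.s0_sq + 8 * s_sq) / (prior.d0 + 8)
            assert min(s_sq, prior.s0_sq) <= post <= max(s_sq, prior.s0_sq)

    def test_abs_t_monotone_in_abs_delta(self):
        prior = PriorEstimate(d0=4.0, s0_sq=0.25)
        ts = [
            abs(
                moderated_t(self.fit_for(d, 0.5), prior, ("CA1", "WT")).loc["g", "t_mod"]
            )
            for d in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(a < b for a, b in zip(ts, ts[1:]))


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_hand_example_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_all_equal_and_singleton(self):
        assert np.allclose(bh_adjust(np.full(7, 0.2)), 0.2)
        assert bh_adjust(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_matches_literal_definition_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_permutation_equivariance_and_bounds(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= p.min())
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.2]))


class TestClassifyAndFoldChange:
    def test_boundary_q_is_not_called(self):
        df = pd.DataFrame(
            {
                "log2fc": [2.0, -2.0],
                "t_mod": [5.0, -5.0],
                "p_value": [0.005, 0.001],
                "degenerate": [False, False],
            },
            index=["g1", "g2"],
        )
        # q for g1 works out to exactly the threshold -> direction 0
        out = classify_de(df, q_threshold=0.005)
        assert out.loc["g1", "q_value"] == pytest.approx(0.005)
        assert out.loc["g1", "direction"] == 0
        assert out.loc["g2", "direction"] == -1

    def test_signed_linear_convention(self):
        assert signed_linear_fold_change(1.0) == pytest.approx(2.0)
        assert signed_linear_fold_change(-1.0) == pytest.approx(-2.0)
        assert signed_linear_fold_change(0.0) == pytest.approx(1.0)
        arr = signed_linear_fold_change(np.array([2.0, -3.0]))
        assert np.allclose(arr, [4.0, -8.0])
        assert np.all(np.abs(arr) >= 1.0)

    def test_all_null_yields_almost_no_calls(self, design):
        expr, _ = generate_expression_matrix(design, n_genes=400, n_de=0, seed=3)
        results = run_de(expr, design)
        total = sum((df["direction"] != 0).sum() for df in results.values())
        assert total == 0

    def test_planted_effects_recovered_with_high_recall(self, design):
        expr, truth = generate_expression_matrix(
            design, n_genes=500, n_de=50, effect_size_log2=2.0,
            noise_sd_log2=0.3, de_sign=+1, seed=5,
        )
        results = run_de(expr, design)
        up_all, down_all = consistent_de_sets(results)
        planted = set(truth.de_genes)
        assert len(set(up_all.members) & planted) >= 0.95 * len(planted)
        assert len(down_all) == 0


def test_pipeline_matches_limma_oracle(tmp_path, design):
    """Full moderated-t route vs limma lmFit/contrasts.fit/eBayes."""
    rng = np.random.default_rng(13)
    n_genes = 150
    # heteroscedastic genes so the prior df comes out finite
    gene_sd = np.sqrt(0.05 * 6 / rng.chisquare(6, n_genes))
    theta = rng.uniform(6, 12, n_genes)
    values = theta[:, None] + rng.normal(0, 1, (n_genes, 12)) * gene_sd[:, None]
    expr = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(n_genes)],
            columns=design["array_id"].tolist(),
        )
    )
    expr_path = tmp_path / "expr.tsv"
    expr.values.to_csv(expr_path, sep="\t")
    conditions = ",".join(f'"{c}"' for c in design["condition"])
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{expr_path}", row.names=1, check.names=FALSE))
        cond <- factor(c({conditions}), levels=c("WT","CA1","CA2","CA3"))
        dm <- model.matrix(~0 + cond)
        colnames(dm) <- levels(cond)
        fit <- lmFit(x, dm)
        cm <- makeContrasts(CA1-WT, CA2-WT, CA3-WT, levels=dm)
        eb <- eBayes(contrasts.fit(fit, cm))
        cat(sprintf("%.12g", eb$df.prior), "\\n")
        cat(sprintf("%.12g", eb$s2.prior), "\\n")
        write.table(cbind(eb$t, eb$p.value), "{tmp_path}/limma.tsv", sep="\\t")
    """)
    proc = subprocess.run(
        ["Rscript", "-e", script], check=True, capture_output=True, text=True
    )
    fit = fit_group_means(expr, design)
    prior = estimate_prior(fit.residual_variance, fit.residual_df)
    limma = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    d0_r, s0_r = (float(v) for v in proc.stdout.split())
    assert prior.d0 == pytest.approx(d0_r, rel=1e-6)
    assert prior.s0_sq == pytest.approx(s0_r, rel=1e-6)
    for i, contrast in enumerate([("CA1", "WT"), ("CA2", "WT"), ("CA3", "WT")]):
        ours = moderated_t(fit, prior, contrast)
        assert np.allclose(ours["t_mod"], limma.iloc[:, i], rtol=1e-8)
        assert np.allclose(ours["p_value"], limma.iloc[:, 3 + i], rtol=1e-8)
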