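"""NB GLM fitting, dispersion estimation, QL F-test and BH correction."""

import numpy as np
import pytest
from scipy.optimize import minimize

import crossmas.glmql as gq
from crossmas import (
    CountMatrix,
    SimulationConfig,
    ValidationError,
    bh_adjust,
    build_design,
    estimate_dispersions,
    fit_nb_glm,
    ql_ftest,
    simulate_experiment,
    tmm_factors,
)


def bh_oracle(p):
    """Direct enumeration of the step-up rule min_{k>=i} p_(k) * m / k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[k]] * m / (k + 1) for k in range(pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


@pytest.fixture(scope="module")
def three_group_design():
    n = 12
    X = np.zeros((n, 3))
    X[:, 0] = 1
    X[4:8, 1] = 1
    X[8:, 2] = 1
    return X


class TestFitNbGlm:
    def test_intercept_only_closed_form(self):
        o = np.log(2.5e5)
        fit = fit_nb_glm(np.array([2, 4, 6]), np.ones((3, 1)), np.full(3, o), 0.1)
        assert abs(fit.coefficients[0] - (np.log(4) - o)) < 1e-8
        assert fit.df_residual == 2

    def test_poisson_limit_two_group_closed_form(self):
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        y = np.r_[[10.0] * 4, [20.0] * 4]
        fit = fit_nb_glm(y, X, np.zeros(8), 1e-8)
        assert abs(fit.coefficients[0] - np.log(10)) < 1e-6
        assert abs(fit.coefficients[1] - np.log(2)) < 1e-6

    def test_poisson_limit_matches_poisson_glm_oracle(self, three_group_design):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        X = three_group_design
        y = rng.poisson(np.exp(4 + X[:, 1] - 0.5 * X[:, 2]))
        fit = fit_nb_glm(y, X, np.zeros(12), gq.DISPERSION_FLOOR)
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.coefficients, oracle.params, atol=1e-6)

    def test_matches_derivative_free_mle(self, three_group_design):
        X = three_group_design
        rng = np.random.default_rng(5)
        phi = 0.1
        worst = 0.0
        for _ in range(50):
            mu = np.exp(rng.normal(np.log(200), 1)) * np.exp(X @ rng.normal(0, 0.5, 3))
            y = rng.poisson(rng.gamma(1 / phi, phi * mu))
            fit = fit_nb_glm(y, X, np.zeros(12), phi)

            def nll(b):
                m = np.exp(X @ b)
                return -float(gq.nb_loglik(y[None], m[None], np.array([phi]))[0])

            res = minimize(
                nll, fit.coefficients + rng.normal(0, 0.05, 3),
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000, maxfev=20000),
            )
            worst = max(worst, float(np.max(np.abs(res.x - fit.coefficients))))
        assert worst < 1e-5

    def test_all_zero_group_stays_finite(self, three_group_design):
        y = np.r_[[5, 7, 6, 4], [0, 0, 0, 0], [6, 5, 8, 7]]
        fit = fit_nb_glm(y, three_group_design, np.zeros(12), 0.05)
        assert np.all(np.isfinite(fit.coefficients))
        assert np.all(np.abs(fit.coefficients) <= 50)

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValidationError, match="rank"):
            fit_nb_glm(np.arange(6), X, np.zeros(6), 0.1)

    def test_deviance_nonnegative(self, three_group_design):
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.poisson(50, 12)
            fit = fit_nb_glm(y, three_group_design, np.zeros(12), 0.2)
            assert fit.deviance >= 0


@pytest.fixture(scope="module")
def simulated(three_group_design):
    rng = np.random.default_rng(10)
    G, phi = 2000, 0.1
    X = three_group_design
    mu = np.exp(rng.normal(5, 1.5, G))[:, None] * np.ones((1, 12))
    Y = rng.poisson(rng.gamma(1 / phi, phi * mu)).astype(int)
    Y = Y[Y.sum(axis=1) > 0]
    return Y, X


class TestDispersions:

    def test_common_dispersion_recovers_truth(self, simulated):
        Y, X = simulated
        disp = estimate_dispersions(Y, X, np.zeros(12))
        assert 0.07 <= disp.common_dispersion <= 0.13

    def test_poisson_data_gives_tiny_dispersion(self, three_group_design):
        rng = np.random.default_rng(11)
        G = 1000
        mu = np.exp(rng.normal(5, 1.5, G))
        Y = rng.poisson(mu[:, None] * np.ones((1, 12))).astype(int)
        Y = Y[Y.sum(axis=1) > 0]
        disp = estimate_dispersions(Y, three_group_design, np.zeros(12))
        assert disp.common_dispersion <= 0.01

    def test_squeezing_moves_toward_trend(self, simulated):
        Y, X = simulated
        disp = estimate_dispersions(Y, X, np.zeros(12))
        # squeezed values lie between raw and trend for every gene
        lo = np.minimum(disp.ql_dispersion_raw, disp.ql_trend) - 1e-12
        hi = np.maximum(disp.ql_dispersion_raw, disp.ql_trend) + 1e-12
        assert np.all((disp.ql_dispersion >= lo) & (disp.ql_dispersion <= hi))
        assert disp.prior_df >= 0

    def test_zero_prior_df_means_no_shrinkage(self, simulated):
        Y, X = simulated
        disp = estimate_dispersions(Y, X, np.zeros(12))
        df_res = 12 - 3
        unshrunk = (df_res * disp.ql_dispersion_raw + 0.0 * disp.ql_trend) / df_res
        assert np.allclose(unshrunk, disp.ql_dispersion_raw)

    def test_too_few_residual_df_raises(self):
        X = np.column_stack([np.ones(4), np.r_[0, 0, 1, 1],
                             np.r_[0, 1, 0, 1]])
        with pytest.raises(ValidationError, match="residual df"):
            estimate_dispersions(np.ones((5, 4), dtype=int), X, np.zeros(4))


class TestQLFTest:
    def test_null_gene_f_zero_p_one(self, three_group_design):
        # constant gene: deviance difference between nested fits is ~0
        X = three_group_design
        Y = np.full((3, 12), 50)
        disp = gq.DispersionModel(
            common_dispersion=0.1,
            genewise_dispersion=np.full(3, 0.1),
            trended_dispersion=np.full(3, 0.1),
            ql_dispersion=np.ones(3),
            ql_dispersion_raw=np.ones(3),
            ql_trend=np.ones(3),
            prior_df=10.0,
            ave_log_cpm=np.zeros(3),
        )
        table = ql_ftest(Y, X, np.zeros(12), disp, "kd")
        assert np.allclose(table["p_raw"], 1.0, atol=1e-6)
        assert np.allclose(table["log2fc"], 0.0, atol=1e-6)

    def test_planted_effect_detected(self, three_group_samples):
        cfg = SimulationConfig(
            n_genes=400, n_per_group=4, planted_lfc_magnitude=3.0,
            dispersion_mean=0.05, class_counts={"kd_up": 5}, seed=3,
        )
        counts, samples, truth = simulate_experiment(cfg)
        keep = counts.counts.sum(axis=1) > 0
        cmx = CountMatrix(
            tuple(g for g, k in zip(counts.gene_ids, keep) if k),
            counts.sample_ids, counts.counts[keep],
        )
        norm = tmm_factors(cmx)
        X, _ = build_design(samples)
        off = np.log(norm.effective_lib_sizes)
        disp = estimate_dispersions(cmx, X, off)
        table = ql_ftest(cmx, X, off, disp, "kd").set_index("gene_id")
        planted = truth.loc[truth["class"] == "kd_up", "gene_id"]
        assert (table.loc[planted, "p_bh"] < 0.05).all()
        assert (table.loc[planted, "log2fc"] > 1).all()

    def test_direction_and_significance_flags_consistent(self, three_group_samples):
        cfg = SimulationConfig(n_genes=300, n_per_group=4,
                               class_counts={"kd_up": 10, "kd_down": 10}, seed=4)
        counts, samples, _ = simulate_experiment(cfg)
        keep = counts.counts.sum(axis=1) > 0
        cmx = CountMatrix(
            tuple(g for g, k in zip(counts.gene_ids, keep) if k),
            counts.sample_ids, counts.counts[keep],
        )
        norm = tmm_factors(cmx)
        X, _ = build_design(samples)
        off = np.log(norm.effective_lib_sizes)
        disp = estimate_dispersions(cmx, X, off)
        t = ql_ftest(cmx, X, off, disp, "oe", alpha=0.05, lfc_threshold=1.0)
        sig = (t["p_bh"] < 0.05) & (t["log2fc"].abs() > 1.0)
        assert (t["significant"] == sig).all()
        assert (t.loc[t["direction"] == "up", "log2fc"] > 0).all()
        assert (t.loc[t["direction"] == "down", "log2fc"] < 0).all()
        assert (t["p_bh"] >= t["p_raw"] - 1e-15).all()


class TestBH:
    def test_single_and_equal_values(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        p = np.full(7, 0.2)
        assert np.allclose(bh_adjust(p), p)

    def test_worked_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(1e-12, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=0, rtol=1e-12)

    def test_monotone_capped_order_preserving(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 100)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.2]))
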