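"""Unit tests for the covariance-structure engine: implied moments, the
casewise (FIML) likelihood, estimation, fit indices, modification indices,
model comparison and the small statistical utilities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from neurosem.sem import (bh_fdr, build_model, compare_nested, congruence,
                          fiml_loglik, fit_model, implied_moments,
                          incremental_fit_indices, modification_indices,
                          pca_first_component)


def _exact_corr_data(R, n=50_000, seed=0, columns=None):
    """Data whose sample correlation matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, R.shape[0]))
    X = X - X.mean(0)
    C = np.linalg.cholesky(np.cov(X.T, bias=True))
    X = X @ np.linalg.inv(C).T @ np.linalg.cholesky(R).T
    cols = columns or [f"v{i}" for i in range(R.shape[0])]
    return pd.DataFrame(X, columns=cols)


# ---------------------------------------------------------------------------
# model building / df accounting
# ---------------------------------------------------------------------------

class TestBuildModel:
    def test_parameter_and_df_count_single_factor(self):
        m = build_model("g =~ a + b + c + d")
        # 4 loadings + 4 residual variances + 4 intercepts
        assert m.npar == 12
        assert m.n_moments == 4 * 5 // 2 + 4
        assert m.df == 2

    def test_residual_covariance_costs_one_df(self):
        m0 = build_model("g =~ a + b + c + d")
        m1 = build_model("g =~ a + b + c + d\na ~~ c")
        assert m1.df == m0.df - 1

    def test_unknown_variable_and_cycle_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            build_model("g =~ a + b\ng ~ nonexistent_predictor",
                        variables=["a", "b"])
        with pytest.raises(ValueError, match="cyclic"):
            build_model("f =~ a + b\nh =~ c + d\nf ~ h\nh ~ f")

    def test_two_group_loading_equality_frees_drop(self, factor_frame):
        df = factor_frame(n=4000, seed=3)
        df["grp"] = np.where(np.arange(len(df)) % 2 == 0, "a", "b")
        m = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                        "tmtb_time")
        free = fit_model(m, df, group="grp", compute_se=False,
                         compute_fit=False)
        con = fit_model(m, df, group="grp", equal=("loadings",),
                        compute_se=False, compute_fit=False)
        # 4 loadings shared (-4) but group-2 latent variance freed (+1)
        assert free.npar - con.npar == 3


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

class TestImpliedMoments:
    def test_single_factor_closed_form(self):
        a, b, u, v = 0.7, 0.4, 0.3, 0.6
        m = build_model("f =~ x + y", meanstructure=False)
        Sigma, mu = implied_moments(m, {"f=~x": a, "f=~y": b,
                                        "x~~x": u, "y~~y": v})
        assert np.allclose(Sigma, [[a * a + u, a * b], [a * b, b * b + v]])
        assert np.allclose(mu, 0.0)

    def test_zero_loadings_give_diagonal(self):
        m = build_model("f =~ x + y + z", meanstructure=False)
        theta = {"f=~x": 0, "f=~y": 0, "f=~z": 0,
                 "x~~x": 1, "y~~y": 2, "z~~z": 3}
        Sigma, _ = implied_moments(m, theta)
        assert np.allclose(Sigma, np.diag([1.0, 2.0, 3.0]))

    def test_four_indicator_printed_solution(self):
        # oracle: direct matrix arithmetic lam lam' + residual structure
        lam = np.array([0.505, 0.479, 0.592, -0.666])
        rho = 0.170
        resid_sd = np.sqrt(1 - lam ** 2)
        expected = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        expected[0, 2] = expected[2, 0] = \
            lam[0] * lam[2] + rho * resid_sd[0] * resid_sd[2]
        m = build_model("g =~ mr + sds + vnr + tmtb\nmr ~~ vnr",
                        meanstructure=False)
        theta = {"g=~mr": lam[0], "g=~sds": lam[1], "g=~vnr": lam[2],
                 "g=~tmtb": lam[3],
                 "mr~~mr": 1 - lam[0] ** 2, "sds~~sds": 1 - lam[1] ** 2,
                 "vnr~~vnr": 1 - lam[2] ** 2, "tmtb~~tmtb": 1 - lam[3] ** 2,
                 "mr~~vnr": rho * resid_sd[0] * resid_sd[2]}
        Sigma, _ = implied_moments(m, theta)
        assert np.allclose(Sigma, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# FIML likelihood
# ---------------------------------------------------------------------------

class TestFimlLoglik:
    def test_standard_normal_single_point(self):
        m = build_model("x ~~ 1*x\nx ~ 0*1")
        ll = fiml_loglik(m, {}, pd.DataFrame({"x": [0.0]}))
        assert ll == pytest.approx(-0.918939, abs=1e-6)

    def test_saturated_discrepancy_is_zero(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((500, 2))
        df = pd.DataFrame(Y, columns=["x", "y"])
        S = np.cov(Y.T, bias=True)
        mu = Y.mean(0)
        m = build_model("x ~~ y")
        theta = {"x~~x": S[0, 0], "y~~y": S[1, 1], "x~~y": S[0, 1],
                 "x~1": mu[0], "y~1": mu[1]}
        ll = fiml_loglik(m, theta, df)
        # oracle: closed-form maximum of the saturated Gaussian loglik
        sign, logdet = np.linalg.slogdet(S)
        ll_max = -0.5 * len(Y) * (2 * math.log(2 * math.pi) + logdet + 2)
        assert ll == pytest.approx(ll_max, abs=1e-8)

    def test_missing_cell_reduces_to_marginal_density(self):
        m = build_model("x ~~ y")
        theta = {"x~~x": 2.0, "y~~y": 3.0, "x~~y": 1.0,
                 "x~1": 0.5, "y~1": -0.5}
        df = pd.DataFrame({"x": [1.2], "y": [np.nan]})
        ll = fiml_loglik(m, theta, df)
        # oracle: direct univariate normal density
        expect = -0.5 * (math.log(2 * math.pi * 2.0)
                         + (1.2 - 0.5) ** 2 / 2.0)
        assert ll == pytest.approx(expect, abs=1e-10)

    def test_subject_with_no_observed_variable_rejected(self):
        m = build_model("x ~~ y")
        df = pd.DataFrame({"x": [np.nan], "y": [np.nan]})
        with pytest.raises(ValueError, match="no observed"):
            fiml_loglik(m, {"x~~x": 1, "y~~y": 1, "x~~y": 0,
                            "x~1": 0, "y~1": 0}, df)

    def test_pattern_grouping_matches_per_subject_evaluation(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((300, 3))
        Y[rng.random((300, 3)) < 0.3] = np.nan
        Y = Y[~np.isnan(Y).all(axis=1)]
        df = pd.DataFrame(Y, columns=["a", "b", "c"])
        m = build_model("f =~ a + b + c")
        fit = fit_model(m, df, compute_se=False, compute_fit=False)
        theta = dict(zip(fit._internal["objective"].theta_names,
                         fit._internal["theta"]))
        # public per-subject evaluation on the scaled data equals the
        # pattern-grouped loglik used by the optimizer
        obj = fit._internal["objective"]
        gd = obj.groups[0]
        scaled = pd.DataFrame((Y - gd.y_means) / gd.y_sds,
                              columns=["a", "b", "c"])
        assert fiml_loglik(m, theta, scaled) == pytest.approx(
            obj.loglik(fit._internal["theta"]), rel=1e-10)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

class TestFitModel:
    def test_three_indicator_tetrad_closed_form(self):
        R = np.array([[1, .2, .3], [.2, 1, .35], [.3, .35, 1]])
        df = _exact_corr_data(R, n=20_000, seed=1, columns=["a", "b", "c"])
        fit = fit_model(build_model("f =~ a + b + c"), df, compute_se=False)
        lam = fit.loadings("f")
        assert lam["a"] == pytest.approx(math.sqrt(.2 * .3 / .35), abs=1e-4)
        assert lam["b"] == pytest.approx(math.sqrt(.2 * .35 / .3), abs=1e-4)
        assert lam["c"] == pytest.approx(math.sqrt(.3 * .35 / .2), abs=1e-4)
        assert fit.chisq == pytest.approx(0.0, abs=1e-4)

    def test_fiml_equals_complete_data_ml(self):
        """On complete data the casewise likelihood optimum must coincide
        with an independently coded minimizer of the classic ML discrepancy
        over sample moments."""
        R = np.array([[1, .25, .33], [.25, 1, .30], [.33, .30, 1]])
        df = _exact_corr_data(R, n=5_000, seed=4, columns=["a", "b", "c"])
        fit = fit_model(build_model("f =~ a + b + c"), df, compute_se=False)
        S = np.cov(df.to_numpy().T, bias=True)

        def fml(theta):
            lam, psi = theta[:3], theta[3:]
            Sigma = np.outer(lam, lam) + np.diag(psi)
            sign, logdet = np.linalg.slogdet(Sigma)
            if sign <= 0:
                return 1e9
            return logdet + np.trace(np.linalg.solve(Sigma, S))

        res = optimize.minimize(fml, [.5, .5, .5, .5, .5, .5],
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        lam_oracle = res.x[:3] * np.sqrt(
            1 / (res.x[:3] ** 2 + res.x[3:]))
        lam_fit = fit.loadings("f").to_numpy()
        assert np.allclose(np.abs(lam_fit), np.abs(lam_oracle), atol=1e-5)

    def test_null_covariance_data(self, factor_frame):
        df = factor_frame(n=8000, loadings=(0, 0, 0, 0), seed=9)
        fit = fit_model(build_model(
            "g =~ matrix_reasoning + symbol_digit + vnr + tmtb_time"), df,
            compute_se=False)
        # under the null only the products lam_i*lam_j are pinned (to ~0),
        # so individual loadings wander at the sqrt scale of sampling noise
        assert np.all(np.abs(fit.loadings("g").to_numpy()) < 0.2)
        assert fit.chisq < 15  # ~chi2(df=2) under the null

    def test_rescaling_invariance_of_standardized_solution(self,
                                                           factor_frame):
        df = factor_frame(n=6000, resid_corr=0.17, seed=5)
        m = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                        "tmtb_time\nmatrix_reasoning ~~ vnr")
        fit1 = fit_model(m, df, compute_se=False, compute_fit=False)
        df2 = df.copy()
        df2["vnr"] = df2["vnr"] * 1000.0 + 77.0
        fit2 = fit_model(m, df2, compute_se=False, compute_fit=False)
        assert np.allclose(fit1.params["std"], fit2.params["std"],
                           atol=1e-6)

    def test_variable_reordering_invariance(self, factor_frame):
        df = factor_frame(n=6000, seed=6)
        m1 = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                         "tmtb_time")
        m2 = build_model("g =~ tmtb_time + vnr + symbol_digit + "
                         "matrix_reasoning")
        f1 = fit_model(m1, df, compute_se=False)
        f2 = fit_model(m2, df, compute_se=False)
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-9)
        for t in ("vnr", "tmtb_time"):
            assert f1.loadings("g")[t] == pytest.approx(
                f2.loadings("g")[t], abs=1e-5)

    def test_heywood_case_flagged_not_fatal(self):
        rng = np.random.default_rng(8)
        # 2 strongly redundant indicators + 1 weak: drives a residual
        # variance negative in small samples
        g = rng.standard_normal(60)
        df = pd.DataFrame({
            "a": 0.98 * g + 0.05 * rng.standard_normal(60),
            "b": 0.98 * g + 0.05 * rng.standard_normal(60),
            "c": 0.2 * g + rng.standard_normal(60)})
        fit = fit_model(build_model("f =~ a + b + c"), df,
                        compute_se=False, compute_fit=False)
        assert fit is not None  # converged or flagged, never raised


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

class TestFitIndices:
    def test_saturated_model(self, factor_frame):
        df = factor_frame(n=2000, loadings=(0.6, 0.5), seed=10,
                          columns=("x", "y"))
        fit = fit_model(build_model("x ~~ y"), df, compute_se=False)
        assert fit.df == 0
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0

    def test_incremental_formula_worked_example(self):
        cfi, tli, rmsea = incremental_fit_indices(50, 5, 1000, 10, 1000)
        assert cfi == pytest.approx(0.9545, abs=2e-4)
        assert tli == pytest.approx(0.9091, abs=2e-4)
        assert rmsea == pytest.approx(0.0949, abs=2e-4)

    def test_aic_and_sabic_definitions(self, factor_frame):
        df = factor_frame(n=1000, seed=11)
        fit = fit_model(build_model(
            "g =~ matrix_reasoning + symbol_digit + vnr + tmtb_time"), df,
            compute_se=False)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.npar)
        assert fit.sabic == pytest.approx(
            -2 * fit.loglik + fit.npar * math.log((fit.n + 2) / 24))


# ---------------------------------------------------------------------------
# modification indices and nested comparison
# ---------------------------------------------------------------------------

class TestModificationIndices:
    def test_free_candidate_reports_zero(self, factor_frame):
        df = factor_frame(n=3000, resid_corr=0.17, seed=12)
        m = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                        "tmtb_time\nmatrix_reasoning ~~ vnr")
        fit = fit_model(m, df, compute_se=False, compute_fit=False)
        mis = modification_indices(
            fit, candidates=[("matrix_reasoning", "vnr")])
        assert mis[0].mi == 0.0

    def test_top_candidate_and_refit_agreement(self, factor_frame):
        """The generating residual correlation must surface as the top MI,
        and the MI must match the actual chi-square drop from freeing it
        (within 10%, large n)."""
        df = factor_frame(n=50_000, resid_corr=0.17, seed=13)
        base = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                           "tmtb_time")
        fit0 = fit_model(base, df, compute_se=False, compute_fit=False)
        mis = modification_indices(fit0)
        assert mis[0].parameter == "matrix_reasoning~~vnr"
        freed = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                            "tmtb_time\nmatrix_reasoning ~~ vnr")
        fit1 = fit_model(freed, df, compute_se=False, compute_fit=False)
        dchi = 2 * (fit1.loglik - fit0.loglik)
        assert mis[0].mi == pytest.approx(dchi, rel=0.10)


class TestCompareNested:
    def test_identical_models(self, factor_frame):
        df = factor_frame(n=2000, seed=14)
        m = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                        "tmtb_time")
        f1 = fit_model(m, df, compute_se=False)
        f2 = fit_model(m, df, compute_se=False)
        comp = compare_nested(f1, f2)
        assert comp.delta_chisq == pytest.approx(0.0, abs=1e-6)
        assert comp.pvalue == 1.0

    def test_non_nested_rejected(self, factor_frame):
        df = factor_frame(n=2000, seed=15)
        small = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                            "tmtb_time")
        big = build_model("g =~ matrix_reasoning + symbol_digit + vnr + "
                          "tmtb_time\nmatrix_reasoning ~~ vnr")
        with pytest.raises(ValueError, match="nested"):
            compare_nested(fit_model(small, df, compute_se=False),
                           fit_model(big, df, compute_se=False))


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Explicit step-up enumeration."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    @pytest.mark.parametrize("p, expected", [
        ([0.01], [0.01]),
        ([0.01, 0.02, 0.04, 0.05], [0.04, 0.04, 0.05, 0.05]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_worked_examples(self, p, expected):
        assert np.allclose(bh_fdr(p), expected)

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_oracle_and_monotonicity(self, p):
        q = bh_fdr(p)
        assert np.allclose(q, _bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCongruence:
    def test_identical_vectors(self):
        x = np.array([0.5, -0.7, 0.2])
        assert congruence(x, x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert congruence([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_printed_age_group_vectors(self):
        x = [0.506, 0.539, 0.614, -0.719]
        y = [0.522, 0.492, 0.569, -0.701]
        assert round(congruence(x, y), 2) == 1.00

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            congruence([0, 0], [1, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=2,
                    max_size=8),
           st.floats(min_value=0.1, max_value=10))
    def test_bounded_and_scale_invariant(self, x, c):
        x = np.asarray(x)
        if np.linalg.norm(x) < 1e-6:
            return
        y = x[::-1].copy()
        phi = congruence(x, y)
        assert -1 - 1e-9 <= phi <= 1 + 1e-9
        assert congruence(c * x, y) == pytest.approx(phi, abs=1e-9)


class TestPcaFirstComponent:
    def test_identity_correlation(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.standard_normal((50_000, 5)))
        _, prop = pca_first_component(df)
        assert prop == pytest.approx(1 / 5, abs=0.02)

    def test_two_variable_closed_form(self):
        rho = 0.42
        R = np.array([[1, rho], [rho, 1]])
        df = _exact_corr_data(R, n=5_000, seed=17)
        _, prop = pca_first_component(df)
        assert prop == pytest.approx((1 + rho) / 2, abs=1e-6)

    def test_collinear_variables(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(1000)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        _, prop = pca_first_component(df)
        assert prop == pytest.approx(1.0, abs=1e-9)
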