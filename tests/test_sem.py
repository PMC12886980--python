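"""SEM engine: RAM construction, F_ML, estimation, indices, effects, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stuntsem.sem import (
    build_ram,
    cfa,
    effects,
    estimate,
    fit_statistics,
    fml,
    implied_sigma,
    parse_model,
    path_analysis,
    simulate_data,
)
from stuntsem.sem.fitstats import indices_from_chi_square, srmr
from stuntsem.sem.model import SemModelSpec
from stuntsem.sem.ram import fml_and_grad


def _random_spd(rng, p):
    A = rng.standard_normal((p, p))
    return A @ A.T + p * np.eye(p)


class TestSpecAndRam:
    def test_one_factor_four_indicators_parameter_count(self):
        spec = parse_model("measurement:\n  F =~ a b c d\n")
        ram = build_ram(spec)
        loadings = [fp for fp in ram.free if fp.kind == "loading"]
        assert len(loadings) == 3  # first loading fixed to 1
        assert ram.n_free == 8  # 3 loadings + 4 residuals + 1 factor variance
        assert ram.df == 2

    def test_path_only_model_selects_all_variables(self):
        spec = parse_model("structural:\n  y ~ x z\n")
        ram = build_ram(spec)
        assert set(ram.observed) == {"x", "y", "z"}
        assert len(ram.obs_idx) == len(ram.variables)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            parse_model("structural:\n  y ~ x\n  x ~ y\n")

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            SemModelSpec(structural=(("y", "x"), ("y", "x")))

    def test_text_round_trip(self):
        text = (
            "measurement:\n  Neuro =~ comm ps pes fm gm\n"
            "structural:\n  Neuro ~ SES haz\n  haz ~ SES\n"
            "variances:\n  comm ~~ ps\n  pes ~~ pes = 2.5\n"
        )
        spec = parse_model(text)
        again = parse_model(spec.to_text())
        assert again == spec
        assert spec.fixed[("pes", "pes")] == 2.5

    def test_implied_sigma_no_edges(self):
        spec = SemModelSpec(structural=(("y", "x"),))
        ram = build_ram(spec)
        # theta order: y~x path, then variances
        names = ram.param_names()
        theta = np.zeros(ram.n_free)
        theta[names.index("y~~y")] = 2.0
        theta[names.index("x~~x")] = 3.0
        sigma = implied_sigma(ram, theta)
        np.testing.assert_allclose(sigma, np.diag([3.0, 2.0])[[1, 0]][:, [1, 0]])

    def test_implied_sigma_single_path_hand_algebra(self):
        spec = SemModelSpec(structural=(("y", "x"),))
        ram = build_ram(spec)
        names = ram.param_names()
        theta = np.zeros(ram.n_free)
        beta, phi, psi = 0.7, 2.0, 0.5
        theta[names.index("y~x")] = beta
        theta[names.index("x~~x")] = phi
        theta[names.index("y~~y")] = psi
        sigma = implied_sigma(ram, theta)
        expected = {
            ("x", "x"): phi,
            ("x", "y"): beta * phi,
            ("y", "y"): beta**2 * phi + psi,
        }
        obs = list(ram.observed)
        for (a, b), v in expected.items():
            assert sigma[obs.index(a), obs.index(b)] == pytest.approx(v, abs=1e-12)


class TestFml:
    def test_identity(self, rng):
        S = _random_spd(rng, 4)
        assert fml(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        assert fml(np.eye(2), np.diag([2.0, 2.0])) == pytest.approx(2 * np.log(2) - 1, abs=1e-12)

    def test_rotation_invariance(self, rng):
        S = _random_spd(rng, 3)
        Sigma = _random_spd(rng, 3)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert fml(Q @ S @ Q.T, Q @ Sigma @ Q.T) == pytest.approx(fml(S, Sigma), abs=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=40)
    def test_nonnegative_on_random_spd_pairs(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(2, 6)
        S = _random_spd(rng, p)
        Sigma = _random_spd(rng, p)
        assert fml(S, Sigma) >= -1e-12

    def test_gradient_matches_finite_differences(self, rng):
        spec = parse_model("measurement:\n  F =~ a b c\nstructural:\n  F ~ x\n")
        ram = build_ram(spec)
        S = _random_spd(np.random.default_rng(3), len(ram.observed))
        theta = np.array(
            [0.9 if fp.kind == "loading" else 0.2 if fp.kind in ("path", "cov") else 1.0
             for fp in ram.free]
        )
        f0, g = fml_and_grad(ram, theta, S)
        for k in range(len(theta)):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (fml_and_grad(ram, tp, S)[0] - fml_and_grad(ram, tm, S)[0]) / (2 * h)
            assert g[k] == pytest.approx(fd, abs=1e-5)


class TestEstimate:
    def test_single_regression_reduces_to_ols(self, rng):
        x = rng.standard_normal(400)
        y = 0.8 * x + 0.6 * rng.standard_normal(400)
        data = pd.DataFrame({"x": x, "y": y})
        fit = estimate(parse_model("structural:\n  y ~ x\n"), data)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.theta["y~x"] == pytest.approx(slope, abs=1e-8)
        assert fit.theta["x~~x"] == pytest.approx(np.var(x, ddof=1), abs=1e-8)
        assert fit.grad_norm < 1e-5

    def test_population_covariance_recovers_parameters(self):
        spec = parse_model("measurement:\n  F =~ a b c d\n")
        ram = build_ram(spec)
        truth = {
            "F=~b": 0.8, "F=~c": 0.7, "F=~d": 0.6, "F~~F": 1.2,
            "a~~a": 0.5, "b~~b": 0.6, "c~~c": 0.7, "d~~d": 0.8,
        }
        theta0 = np.array([truth[fp.name] for fp in ram.free])
        sigma0 = implied_sigma(ram, theta0)
        # feed exact population moments as the data moments
        fit_pop = _estimate_with_cov(spec, sigma0, n=1000)
        assert fit_pop.fmin == pytest.approx(0.0, abs=1e-10)
        for name, val in truth.items():
            assert fit_pop.theta[name] == pytest.approx(val, abs=1e-6)

    def test_one_factor_recovery_from_simulated_data(self):
        spec = parse_model("measurement:\n  F =~ a b c d\n")
        truth = {"F=~b": 0.8, "F=~c": 0.7, "F=~d": 0.6, "F~~F": 1.0,
                 "a~~a": 0.5, "b~~b": 0.5, "c~~c": 0.5, "d~~d": 0.5}
        data = simulate_data(spec, truth, 2000, np.random.default_rng(11))
        fit, stats = cfa(spec, data)
        for name in ("F=~b", "F=~c", "F=~d"):
            assert fit.theta[name] == pytest.approx(truth[name], abs=0.08)
        assert stats.cfi >= 0.95

    def test_deterministic_estimation(self, rng):
        spec = parse_model("structural:\n  y ~ x\n  z ~ y\n")
        data = simulate_data(spec, {"y~x": 0.5, "z~y": 0.3}, 500, np.random.default_rng(2))
        f1 = estimate(spec, data)
        f2 = estimate(spec, data)
        pd.testing.assert_series_equal(f1.theta, f2.theta)

    def test_listwise_deletion_reports_n(self, rng):
        spec = parse_model("structural:\n  y ~ x\n")
        data = pd.DataFrame({"x": rng.standard_normal(100), "y": rng.standard_normal(100)})
        data.loc[:9, "x"] = np.nan
        assert estimate(spec, data).n == 90

    def test_insufficient_n_rejected(self, rng):
        spec = parse_model("measurement:\n  F =~ a b c d\n")
        data = pd.DataFrame(rng.standard_normal((6, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="exceed"):
            estimate(spec, data)


def _estimate_with_cov(spec, sigma, n):
    """Fit a spec to an exact covariance matrix via synthetic data with those moments."""
    rng = np.random.default_rng(99)
    p = sigma.shape[0]
    Z = rng.standard_normal((n, p))
    Z -= Z.mean(axis=0)
    # whiten then color so the sample covariance equals sigma exactly
    cov = np.cov(Z, rowvar=False, ddof=1)
    L_inv = np.linalg.inv(np.linalg.cholesky(cov))
    L = np.linalg.cholesky(sigma)
    X = Z @ L_inv.T @ L.T
    return estimate(spec, pd.DataFrame(X, columns=list(spec.observed)))


class TestFitStatistics:
    def test_closed_form_indices(self):
        cfi, tli, rmsea = indices_from_chi_square(20.0, 10, 200.0, 15, 101)
        assert cfi == pytest.approx(0.9459, abs=1e-4)
        assert tli == pytest.approx(0.9189, abs=1e-4)
        assert rmsea == pytest.approx(0.1000, abs=1e-6)

    def test_saturated_model_is_perfect(self, rng):
        spec = parse_model("structural:\n  y ~ x z\n  z ~ x\n")
        data = pd.DataFrame(rng.standard_normal((300, 3)), columns=["x", "y", "z"])
        fit, stats = path_analysis(spec, data)
        assert fit.df == 0
        assert stats.chi_square == pytest.approx(0.0, abs=1e-8)
        assert stats.cfi == 1.0 and stats.rmsea == 0.0
        assert stats.srmr < 1e-8

    def test_population_covariance_gives_ideal_indices(self):
        spec = parse_model("measurement:\n  F =~ a b c d\n")
        ram = build_ram(spec)
        theta0 = np.array(
            [0.8 if fp.kind == "loading" else 1.0 for fp in ram.free]
        )
        sigma0 = implied_sigma(ram, theta0)
        fit = _estimate_with_cov(spec, sigma0, 500)
        stats = fit_statistics(fit)
        assert stats.chi_square == pytest.approx(0.0, abs=1e-6)
        assert stats.cfi == 1.0
        assert stats.rmsea == pytest.approx(0.0, abs=1e-6)
        assert stats.srmr < 1e-6

    def test_srmr_includes_diagonal(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        Sigma = np.array([[1.5, 0.5], [0.5, 1.0]])
        # residuals: diag cell (2-1.5)/2 = 0.25, others 0 -> sqrt(mean([0.0625,0,0]))
        assert srmr(S, Sigma) == pytest.approx(np.sqrt(0.0625 / 3), abs=1e-12)


class TestStandardize:
    def test_standardized_data_leaves_beta_unchanged(self, rng):
        x = rng.standard_normal(2000)
        y = 0.5 * x + rng.standard_normal(2000)
        zx, zy = (x - x.mean()) / x.std(ddof=1), (y - y.mean()) / y.std(ddof=1)
        fit = estimate(parse_model("structural:\n  y ~ x\n"), pd.DataFrame({"x": zx, "y": zy}))
        assert fit.std["y~x"] == pytest.approx(fit.theta["y~x"], abs=1e-7)

    def test_single_path_standardized_equals_pearson_r(self, rng):
        x = rng.standard_normal(1000)
        y = 0.4 * x + rng.standard_normal(1000)
        fit = estimate(parse_model("structural:\n  y ~ x\n"), pd.DataFrame({"x": x, "y": y}))
        assert fit.std["y~x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-8)

    def test_fixed_loading_standardized_in_unit_interval(self):
        spec = parse_model("measurement:\n  F =~ a b c d\n")
        data = simulate_data(
            spec,
            {"F=~b": 0.8, "F=~c": 0.7, "F=~d": 0.6, "F~~F": 1.0,
             "a~~a": 0.5, "b~~b": 0.5, "c~~c": 0.5, "d~~d": 0.5},
            1000,
            np.random.default_rng(4),
        )
        fit, _ = cfa(spec, data)
        # implied: std loading of anchor = sd(F)/sd(a) in (0, 1] with positive residual
        names = [fp.name for fp in fit.ram.free]
        assert all(0 < fit.std[f"F=~{v}"] <= 1 for v in "bcd")


class TestEffects:
    def test_product_rule_on_known_coefficients(self):
        spec = parse_model("structural:\n  M ~ X\n  Y ~ M X\n")
        data = simulate_data(
            spec, {"M~X": 0.5, "Y~M": 0.4, "Y~X": 0.1}, 20000, np.random.default_rng(8)
        )
        fit = estimate(spec, data)
        eff = effects(fit, "X", "Y")
        assert eff.total == pytest.approx(eff.direct + eff.indirect, abs=1e-12)
        assert eff.indirect == pytest.approx(
            fit.theta["M~X"] * fit.theta["Y~M"], abs=1e-10
        )

    def test_no_route_gives_zero_effects(self, rng):
        spec = parse_model("structural:\n  y ~ x\n  z ~ x\n")
        data = pd.DataFrame(rng.standard_normal((200, 3)), columns=["x", "y", "z"])
        fit = estimate(spec, data)
        eff = effects(fit, "y", "z")
        assert eff.direct == eff.indirect == eff.total == 0.0

    def test_source_equal_outcome_rejected(self, rng):
        spec = parse_model("structural:\n  y ~ x\n")
        data = pd.DataFrame(rng.standard_normal((50, 2)), columns=["x", "y"])
        fit = estimate(spec, data)
        with pytest.raises(ValueError):
            effects(fit, "x", "x")

    def test_delta_method_se_close_to_empirical(self):
        spec = parse_model("structural:\n  M ~ X\n  Y ~ M X\n")
        truth = {"M~X": 0.5, "Y~M": 0.4, "Y~X": 0.1}
        estimates, ses = [], []
        for seed in range(60):
            data = simulate_data(spec, truth, 1000, np.random.default_rng(1000 + seed))
            fit = estimate(spec, data)
            eff = effects(fit, "X", "Y")
            estimates.append(eff.indirect)
            ses.append(eff.se_indirect)
        emp = np.std(estimates, ddof=1)
        assert np.mean(estimates) == pytest.approx(0.2, abs=0.05)
        assert abs(np.mean(ses) - emp) / emp < 0.25


class TestCfaAndPath:
    def test_one_factor_fits_worse_than_true_two_factor(self):
        two = parse_model("measurement:\n  F1 =~ a b c\n  F2 =~ d e f\n")
        truth = {"F1=~b": 0.9, "F1=~c": 0.8, "F2=~e": 0.9, "F2=~f": 0.8,
                 "F1~~F2": 0.0}
        data = simulate_data(two, truth, 1500, np.random.default_rng(6))
        one = parse_model("measurement:\n  F =~ a b c d e f\n")
        _, stats_one = cfa(one, data)
        _, stats_two = cfa(two, data)
        assert stats_two.cfi > stats_one.cfi

    def test_three_indicator_factor_is_just_identified(self, rng):
        spec = parse_model("measurement:\n  F =~ a b c\n")
        data = simulate_data(spec, {"F=~b": 0.8, "F=~c": 0.7}, 500, np.random.default_rng(7))
        fit, stats = cfa(spec, data)
        assert fit.df == 0
        assert stats.chi_square == pytest.approx(0.0, abs=1e-7)

    def test_cfa_rejects_structural_edges(self, rng):
        spec = parse_model("measurement:\n  F =~ a b c\nstructural:\n  F ~ x\n")
        with pytest.raises(ValueError):
            cfa(spec, pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcx")))

    def test_recursive_chain_equals_stagewise_ols(self, rng):
        x = rng.standard_normal(800)
        m = 0.6 * x + rng.standard_normal(800)
        y = 0.5 * m + rng.standard_normal(800)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        fit, _ = path_analysis(parse_model("structural:\n  m ~ x\n  y ~ m\n"), data)
        b1 = np.cov(x, m, ddof=1)[0, 1] / np.var(x, ddof=1)
        b2 = np.cov(m, y, ddof=1)[0, 1] / np.var(m, ddof=1)
        assert fit.theta["m~x"] == pytest.approx(b1, abs=1e-7)
        assert fit.theta["y~m"] == pytest.approx(b2, abs=1e-7)

    def test_omitted_path_chi_square_grows_with_n(self):
        gen = parse_model("structural:\n  m ~ x\n  y ~ m x\n")
        truth = {"m~x": 0.5, "y~m": 0.4, "y~x": 0.4}
        wrong = parse_model("structural:\n  m ~ x\n  y ~ m\n")
        chis = {}
        for n in (500, 2000):
            data = simulate_data(gen, truth, n, np.random.default_rng(13))
            _, stats = path_analysis(wrong, data)
            chis[n] = stats.chi_square
        assert chis[2000] > 2.0 * chis[500]

    def test_path_analysis_rejects_latents(self, rng):
        spec = parse_model("measurement:\n  F =~ a b c\n")
        with pytest.raises(ValueError):
            path_analysis(spec, pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc")))
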