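import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid

from thermodiv.bd import (
    RateSpec,
    bd_loglik,
    enumerate_models,
    fit_bd,
    model_table,
    paleo_prepare,
    rtt_curve,
    rtt_temp_regression,
)
from thermodiv.simulate import make_paleo_curve, simulate_bd_tree


def yule_closed_form(tree, lam):
    """Crown-conditioned pure-birth log-likelihood, textbook form."""
    n = tree.n_tips
    return (n - 2) * np.log(lam) - lam * tree.total_length


def riemann_loglik(tree, spec, sampling_f=1.0, step=1e-4):
    """Independent brute-force oracle: fine-grid trapezoid integration."""
    am = tree.node_ages()
    a = tree.arrays
    ages = np.array([am.ages[i] for i in range(a.n_nodes)])
    ages[: a.n_tips] = 0.0
    crown = am.crown_age
    grid = np.linspace(0.0, crown, int(crown / step) + 2)
    lam = spec.lambda_at(grid)
    mu = spec.mu_at(grid)
    r = cumulative_trapezoid(lam - mu, grid, initial=0.0)
    F = cumulative_trapezoid(np.exp(r) * lam, grid, initial=0.0)
    r_at = np.interp(ages, grid, r)
    F_at = np.interp(ages, grid, F)
    inv_f = 1.0 / sampling_f
    ll = a.n_tips * np.log(sampling_f)
    internal = [i for i in range(a.n_nodes) if a.children[i]]
    ll += np.sum(np.log(spec.lambda_at(ages[internal])))
    ll -= np.log(spec.lambda_at([crown])[0])
    for v in range(a.n_nodes):
        p = a.parent[v]
        if p < 0:
            continue
        ll += (r_at[p] - r_at[v]) + 2 * (
            np.log(inv_f + F_at[v]) - np.log(inv_f + F_at[p])
        )
    ll -= 2 * (r_at[a.root] - np.log(inv_f + F_at[a.root]))
    return ll


class TestLoglik:
    @pytest.mark.parametrize("seed", range(5))
    def test_yule_closed_form(self, seed):
        tree, _ = simulate_bd_tree(0.5, 0.0, ("n_tips", 30), seed=seed)
        spec = RateSpec("time", "constant", "zero", lambda0=0.41)
        assert bd_loglik(tree, spec) == pytest.approx(
            yule_closed_form(tree, 0.41), abs=1e-6
        )

    def test_env_on_constant_curve_equals_time_constant(self, bd50):
        curve = make_paleo_curve("constant", dict(temp=12.0))
        env = RateSpec("env", "exponential", "constant",
                       lambda0=0.3 * np.exp(-0.02 * 12.0), alpha=0.02,
                       mu0=0.1, curve=curve)
        ref = RateSpec("time", "constant", "constant", lambda0=0.3, mu0=0.1)
        assert bd_loglik(bd50, env) == pytest.approx(bd_loglik(bd50, ref), abs=1e-6)

    def test_exponential_slope_zero_equals_constant(self, bd50):
        a = RateSpec("time", "exponential", "linear", lambda0=0.3, alpha=0.0,
                     mu0=0.1, beta=0.0)
        b = RateSpec("time", "constant", "constant", lambda0=0.3, mu0=0.1)
        assert bd_loglik(bd50, a) == pytest.approx(bd_loglik(bd50, b), abs=1e-9)

    def test_riemann_oracle_all_env_models(self):
        tree, _ = simulate_bd_tree(0.8, 0.2, ("n_tips", 10), seed=3)
        curve = make_paleo_curve("cramer_like")
        params = dict(lambda0=0.5, alpha=-0.01, mu0=0.1, beta=0.005)
        for spec in enumerate_models("env", curve=curve):
            spec = spec.with_params(
                **{k: v for k, v in params.items() if k in spec.free_params}
            )
            assert bd_loglik(tree, spec) == pytest.approx(
                riemann_loglik(tree, spec), abs=1e-5
            ), spec.name

    def test_sampling_fraction_enters(self, bd50):
        spec = RateSpec("time", "constant", "constant", lambda0=0.3, mu0=0.1)
        full = bd_loglik(bd50, spec, 1.0)
        half = bd_loglik(bd50, spec, 0.5)
        assert half != pytest.approx(full)
        assert bd_loglik(bd50, spec, 0.5) == pytest.approx(
            riemann_loglik(bd50, spec, 0.5, step=5e-4), abs=1e-4
        )

    def test_nonpositive_speciation_penalised(self, bd50):
        spec = RateSpec("time", "linear", "zero", lambda0=0.2, alpha=-0.5)
        assert bd_loglik(bd50, spec) < -1e6

    def test_rejects_non_ultrametric(self):
        from thermodiv.trees import parse_newick
        t = parse_newick("(A:1,B:2);")
        with pytest.raises(ValueError):
            bd_loglik(t, RateSpec("time", "constant", "zero", lambda0=0.3))


class TestEnumerateAndTable:
    def test_twelve_models_per_dependency(self):
        specs = enumerate_models("time")
        assert len(specs) == 12
        assert sum(1 for s in specs if s.mu_family == "zero") == 3

    def test_parameter_counts(self):
        assert RateSpec("time", "constant", "constant").k == 2
        assert RateSpec("time", "exponential", "exponential").k == 4
        assert RateSpec("time", "constant", "zero").k == 1

    def test_akaike_weights_closed_form(self):
        from thermodiv.bd import ModelFitResult
        f1 = ModelFitResult(RateSpec("time", "constant", "zero"), -10.0, 1, 22.0, True, 1.0)
        f2 = ModelFitResult(RateSpec("time", "linear", "zero"), -10.0, 2, 24.0, True, 1.0)
        tab = model_table([f1, f2])
        assert tab["AW"].to_numpy() == pytest.approx([0.7311, 0.2689], abs=1e-4)
        assert tab["AW"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_model_weight_one(self):
        from thermodiv.bd import ModelFitResult
        f = ModelFitResult(RateSpec("time", "constant", "zero"), -10.0, 1, 22.0, True, 1.0)
        assert model_table([f])["AW"].iloc[0] == pytest.approx(1.0)


class TestFit:
    def test_yule_rate_recovery(self):
        hits = 0
        for s in range(15):
            tree, _ = simulate_bd_tree(0.2, 0.0, ("n_tips", 200), seed=s)
            fit = fit_bd(tree, RateSpec("time", "constant", "zero"), n_starts=2, seed=s)
            hits += 0.15 <= fit.spec.lambda0 <= 0.25
        assert hits >= 13

    def test_nested_models_monotone(self, bd50):
        const = fit_bd(bd50, RateSpec("time", "constant", "constant"), n_starts=2, seed=0)
        expo = fit_bd(bd50, RateSpec("time", "exponential", "constant"), n_starts=3, seed=0)
        assert expo.loglik >= const.loglik - 1e-6


class TestPaleoPrepare:
    def test_constant_series(self):
        df = pd.DataFrame({"age_myr": np.linspace(50, 0, 20), "temp_c": 10.0})
        curve = paleo_prepare(df)
        assert np.allclose(curve.temps, 10.0)
        assert curve.interpolator()(200.0) == pytest.approx(10.0)  # clamped

    def test_five_point_mean_midpoint(self):
        df = pd.DataFrame({"age_myr": [5, 4, 3, 2, 1], "temp_c": [1, 2, 3, 4, 5]})
        curve = paleo_prepare(df, window=5)
        assert curve.temps[2] == pytest.approx(3.0)
        # ends shrink symmetrically: first value is its own window
        assert curve.temps[0] == pytest.approx(1.0)
        assert curve.temps[1] == pytest.approx(2.0)

    def test_d18o_affine_conversion(self):
        df = pd.DataFrame({"age_myr": [3, 2, 1], "d18o": [1.0, 2.0, 3.0]})
        curve = paleo_prepare(df, mode="d18o", window=1, d18o_coeffs=(16.5, 4.3))
        assert curve.temps == pytest.approx([16.5 - 4.3, 16.5 - 8.6, 16.5 - 12.9])

    def test_non_monotone_ages_rejected(self):
        df = pd.DataFrame({"age_myr": [3, 5, 1], "temp_c": [1, 2, 3]})
        with pytest.raises(ValueError):
            paleo_prepare(df)

    def test_even_window_rejected(self):
        df = pd.DataFrame({"age_myr": [3, 2, 1], "temp_c": [1, 2, 3]})
        with pytest.raises(ValueError):
            paleo_prepare(df, window=4)


class TestRtt:
    def _fit(self, bd50):
        curve = make_paleo_curve("cramer_like")
        spec = RateSpec("env", "exponential", "zero", lambda0=1.2, alpha=-0.1,
                        curve=curve)
        from thermodiv.bd import ModelFitResult
        return ModelFitResult(spec, 0.0, 2, 4.0, True, 1.0,
                              crown_age=bd50.node_ages().crown_age), curve

    def test_constant_model_flat(self, bd50):
        from thermodiv.bd import ModelFitResult
        spec = RateSpec("time", "constant", "constant", lambda0=0.3, mu0=0.1)
        fit = ModelFitResult(spec, 0.0, 2, 4.0, True, 1.0, crown_age=10.0)
        rtt = rtt_curve(fit, n_slices=100)
        assert len(rtt) == 100
        assert rtt["t"].iloc[0] == pytest.approx(10.0)
        assert rtt["t"].iloc[-1] == pytest.approx(0.0)
        assert rtt["lambda"].nunique() == 1
        assert np.allclose(rtt["r"], 0.2)

    def test_cooling_curve_rate_rises_to_present(self, bd50):
        fit, curve = self._fit(bd50)
        rtt = rtt_curve(fit)
        assert rtt["r"].iloc[-1] > rtt["r"].iloc[0]

    def test_regression_recovers_linear_identity(self, bd50):
        fit, curve = self._fit(bd50)
        rtt = rtt_curve(fit)
        T = curve.interpolator()(rtt["t"].to_numpy())
        rtt["r"] = 0.8 - 0.03 * T  # constructed exactly linear
        reg = rtt_temp_regression(rtt, curve)
        assert reg["form"] == "linear"
        assert reg["slope"] == pytest.approx(-0.03, abs=1e-8)
        assert reg["r2"] == pytest.approx(1.0, abs=1e-10)

    def test_regression_recovers_exponential(self, bd50):
        fit, curve = self._fit(bd50)
        rtt = rtt_curve(fit)
        T = curve.interpolator()(rtt["t"].to_numpy())
        rng = np.random.default_rng(0)
        rtt["r"] = 0.5 * np.exp(-0.1 * T) + rng.normal(0, 1e-5, len(T))
        reg = rtt_temp_regression(rtt, curve)
        assert reg["form"] == "exponential"
        assert reg["slope"] == pytest.approx(-0.1, abs=1e-3)

    def test_constant_rate_r2_zero(self, bd50):
        fit, curve = self._fit(bd50)
        rtt = rtt_curve(fit)
        rtt["r"] = 0.25
        reg = rtt_temp_regression(rtt, curve)
        assert reg["r2"] == pytest.approx(0.0, abs=1e-6)
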