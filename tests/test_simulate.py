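import numpy as np
import pytest

from dthtest import (
    NBScenario,
    NormalScenario,
    gamma_kappa,
    run_study,
    simulate_continuous,
    simulate_negbin,
    simulate_normal,
)


class TestGammaKappa:
    def test_closed_forms(self):
        # 2a = 0.5: (Gamma(1)/Gamma(1/2))^-2 = pi
        assert gamma_kappa(0.25) == pytest.approx(np.pi, rel=1e-12)
        # 2a = 1: (Gamma(3/2)/Gamma(1))^-2 = 4/pi
        assert gamma_kappa(0.5) == pytest.approx(4 / np.pi, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            gamma_kappa(0.0)
        with pytest.raises(ValueError):
            gamma_kappa(-1.0)

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 2.5])
    def test_monte_carlo_unit_expected_root_sum(self, alpha, rng):
        """kappa is defined so E[sqrt(v_i + v_j)] = 1 for iid Gamma draws."""
        k = gamma_kappa(alpha)
        v = rng.gamma(alpha, k, size=(2, 1_000_000))
        s = np.sqrt(v.sum(axis=0))
        se = s.std() / 1000.0
        assert s.mean() == pytest.approx(1.0, abs=3 * se)


class TestNormalScenarios:
    @pytest.mark.parametrize("scenario", ["S0", "S1", "S2", "S3"])
    @pytest.mark.parametrize("G", [2, 3, 5])
    def test_theta_zero_collapses_to_identical_groups(self, scenario, G):
        params = NormalScenario.balanced(scenario, G, 0.0).mixing_params
        for vals in params.values():
            assert len(set(np.round(vals, 12))) == 1

    @pytest.mark.parametrize("G", [2, 3, 5])
    @pytest.mark.parametrize("theta", [0.0, 0.5, 1.5, 2.0])
    def test_s1_constant_mean_dispersion_constraint(self, G, theta):
        """mu_g + sigma_g^2 / 2 = 3/2 in every group, so E(v) = e^{3/2}."""
        p = NormalScenario.balanced("S1", G, theta).mixing_params
        for mu, s2 in zip(p["mu"], p["sigma2"]):
            assert mu + s2 / 2 == pytest.approx(1.5)

    def test_sample_moments(self):
        spec = NormalScenario(scenario="S1", G=2, theta=0.0,
                              group_sizes=(5000, 5000), d=20)
        table, labels = simulate_normal(spec, seed=123)
        Y = table.values
        # coordinate means ~ 0
        assert abs(Y.mean()) < 0.02
        # mean per-sample variance ~ E(v) = e^{3/2}
        vhat = Y.var(axis=1, ddof=0).mean()
        assert vhat == pytest.approx(np.exp(1.5), rel=0.1)

    def test_balanced_sizes_and_labels(self):
        spec = NormalScenario.balanced("S2", 5, 1.0)
        assert spec.group_sizes == (30,) * 5
        table, labels = simulate_normal(spec, seed=0)
        assert table.values.shape == (150, 500)
        assert labels.group_sizes == {f"g{i}": 30 for i in range(1, 6)}

    def test_invalid_combinations(self):
        with pytest.raises(ValueError):
            NormalScenario.balanced("S9", 2, 0.0)
        with pytest.raises(ValueError):
            NormalScenario.balanced("S1", 4, 0.0)

    def test_seeded_determinism(self):
        spec = NormalScenario.balanced("S0", 3, 1.0, n_total=30, d=10)
        t1, _ = simulate_normal(spec, seed=5)
        t2, _ = simulate_normal(spec, seed=5)
        np.testing.assert_array_equal(t1.values, t2.values)


class TestNBScenarios:
    @pytest.mark.parametrize("scenario", ["S1", "S2", "S3"])
    @pytest.mark.parametrize("G", [2, 3, 5])
    def test_theta_zero_collapses_to_identical_groups(self, scenario, G):
        params = NBScenario.balanced(scenario, G, 0.0).mixing_params
        for vals in params.values():
            assert len(set(np.round(vals, 12))) == 1

    @pytest.mark.parametrize("G", [2, 3, 5])
    def test_s1_constant_mean_overdispersion(self, G):
        """beta_g = alpha_g keeps E(1/r) = alpha/beta = 1 in every group."""
        p = NBScenario.balanced("S1", G, 2.0).mixing_params
        ratio = np.array(p["alpha"]) / np.array(p["beta"])
        np.testing.assert_allclose(ratio, 1.0)

    def test_conditional_moments_fixed_r(self):
        # S3 at theta=0: r = 1 everywhere; Var(Y|r) = mu + mu^2/r
        spec = NBScenario(scenario="S3", G=2, theta=0.0,
                          group_sizes=(2, 2), d=100_000, mu_mean=10.0)
        table, _ = simulate_negbin(spec, seed=3)
        Y = table.values
        assert Y.mean() == pytest.approx(10.0, rel=0.03)
        assert Y.var() == pytest.approx(10.0 + 100.0 / 1.0, rel=0.05)

    def test_unconditional_variance(self):
        # S2 at theta=0: alpha=3, beta=5 -> Var(Y) = mu + mu^2 * alpha/beta
        spec = NBScenario(scenario="S2", G=2, theta=0.0,
                          group_sizes=(500, 500), d=500, mu_mean=10.0)
        table, _ = simulate_negbin(spec, seed=4)
        Y = table.values
        assert Y.mean() == pytest.approx(10.0, rel=0.03)
        assert Y.var() == pytest.approx(10.0 + 100.0 * 3.0 / 5.0, rel=0.10)

    def test_counts_are_nonnegative_integers(self):
        spec = NBScenario.balanced("S1", 2, 1.0, n_total=20, d=50)
        table, _ = simulate_negbin(spec, seed=0)
        assert np.all(table.values >= 0)
        assert np.all(table.values == np.round(table.values))

    def test_seeded_determinism(self):
        spec = NBScenario.balanced("S2", 2, 0.5, n_total=20, d=30)
        t1, _ = simulate_negbin(spec, seed=9)
        t2, _ = simulate_negbin(spec, seed=9)
        np.testing.assert_array_equal(t1.values, t2.values)


class TestContinuous:
    def test_covariate_range_and_shapes(self):
        table, x = simulate_continuous(30, 12, 1.0, seed=2)
        assert table.values.shape == (30, 12)
        assert np.all((x >= 0) & (x <= 1))

    def test_null_slope_gives_homogeneous_dispersion(self):
        t1, _ = simulate_continuous(2000, 5, 0.0, seed=1)
        # with slope 0 every sample has unit dispersion
        assert t1.values.var() == pytest.approx(1.0, rel=0.05)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            simulate_continuous(4, 5, 1.0)


class TestRunStudy:
    def test_tidy_output_shape_and_rates(self):
        df = run_study("normal", ["S3"], [2], [0.0, 1.0],
                       methods=("dth", "go_perm"), n_reps=3, R=19,
                       n_total=16, d=8, seed=0)
        assert len(df) == 4  # 2 cells x 2 methods
        assert set(df.columns) >= {"family", "scenario", "G", "theta",
                                   "method", "rate", "rejections"}
        assert df["rate"].between(0, 1).all()
        assert (df["rejections"] <= 3).all()

    def test_single_rep_rate_is_binary(self):
        df = run_study("negbin", ["S1"], [2], [0.0], methods=("dth",),
                       n_reps=1, R=19, n_total=12, d=20, seed=1)
        assert df["rate"].iloc[0] in (0.0, 1.0)

    def test_determinism(self):
        kwargs = dict(family="normal", scenarios=["S1"], G_values=[2],
                      thetas=[0.5], methods=("dth",), n_reps=2, R=19,
                      n_total=12, d=6, seed=42)
        df1, df2 = run_study(**kwargs), run_study(**kwargs)
        assert df1.equals(df2)

    def test_invalid_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_study("normal", ["S1"], [2], [0.0], methods=("anosim",),
                      n_reps=1, R=9, n_total=10, d=4)
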