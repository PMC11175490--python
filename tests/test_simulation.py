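"""Synthetic populations, mean-function rescaling, and the comparison studies."""

import numpy as np
import pytest

from finestrat import (
    MEAN_FUNCTIONS,
    SimulationConfig,
    collapsed_bias_exact,
    make_pairing,
    make_population,
    rescale,
    run_conditional,
    run_unconditional,
)
from finestrat.exceptions import ConfigError, UndefinedRescaleError


class TestRescale:
    @pytest.mark.parametrize("name", sorted(MEAN_FUNCTIONS))
    def test_range_is_zero_to_two(self, name):
        mu = rescale(name)
        grid = np.linspace(0, 1, 100_001)
        vals = mu(grid)
        assert float(vals.min()) == pytest.approx(0.0, abs=1e-6)
        assert float(vals.max()) == pytest.approx(2.0, abs=1e-6)

    def test_linear_rescales_to_2x(self):
        mu = rescale("linear")
        x = np.array([0.0, 0.25, 0.5, 1.0])
        np.testing.assert_allclose(mu(x), 2 * x, atol=1e-12)
        assert mu(1.0) == pytest.approx(2.0)

    def test_constant_function_rejected(self):
        with pytest.raises(UndefinedRescaleError):
            rescale(lambda x: np.full_like(np.asarray(x, float), 3.0))

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigError):
            rescale("cubic")


class TestMakePopulation:
    def test_noiseless_population_equals_mean_on_grid(self):
        H, N = 10, 100
        pop = make_population(N, H, sigma=0.0, mean_fn="linear", rng=0)
        mu = rescale("linear")
        assert pop.n_strata == H
        np.testing.assert_array_equal(pop.sizes, N // H)
        for i, s in enumerate(pop.strata, start=1):
            assert s.x == pytest.approx(i / H)
            np.testing.assert_allclose(s.y, mu(i / H))
            assert s.total == pytest.approx((N / H) * mu(i / H))

    def test_indivisible_sizes_rejected(self):
        with pytest.raises(ConfigError):
            make_population(100, 7, 0.25, "linear", rng=0)

    def test_noise_has_unit_variance_at_scale(self):
        pop = make_population(3000, 100, sigma=1.0, mean_fn="linear", rng=42)
        mu = rescale("linear")
        e = np.concatenate([s.y - mu(s.x) for s in pop.strata])
        # var(e) ~ 1 within 3 standard errors of a chi-square based estimate
        se = np.sqrt(2 / (e.size - 1))
        assert abs(e.var(ddof=1) - 1.0) < 3 * se

    def test_unit_scores_uniform_within_stratum_cells(self):
        H = 20
        pop = make_population(400, H, 0.1, "cycle1", rng=1)
        for i, s in enumerate(pop.strata, start=1):
            assert np.all(s.unit_x > (i - 1) / H)
            assert np.all(s.unit_x <= i / H + 1e-12)


class TestUnconditional:
    def test_single_replicate_rmse_equals_abs_bias(self):
        cfg = SimulationConfig(N=200, H=20, sigma=0.25, h=0.06, R=1, B=50, seed=3)
        res = run_unconditional(cfg)
        for _, row in res.metrics.iterrows():
            assert row["rmse"] == pytest.approx(abs(row["bias"]))

    def test_rmse_dominates_bias_and_cv_nonnegative(self):
        cfg = SimulationConfig(N=500, H=50, sigma=0.25, h=0.03, R=40, B=50, seed=4)
        res = run_unconditional(cfg)
        for _, row in res.metrics.iterrows():
            assert row["rmse"] >= abs(row["bias"]) - 1e-12
            assert row["cv"] >= 0.0

    def test_extending_replicates_preserves_prefix(self):
        base = dict(N=200, H=20, sigma=0.25, h=0.06, B=30, seed=9)
        short = run_unconditional(SimulationConfig(R=10, **base))
        long = run_unconditional(SimulationConfig(R=20, **base))
        for est in ("collapsed", "kernel", "bootstrap"):
            np.testing.assert_array_equal(
                short.replicates[est], long.replicates[est].iloc[:10]
            )

    def test_noiseless_collapsed_bias_matches_closed_form(self):
        """sigma = 0: var(t_hat) = 0 and the empirical collapsed bias is exactly
        the closed-form bias evaluated on the true stratum totals."""
        cfg = SimulationConfig(N=200, H=20, sigma=0.0, h=0.06, R=5, B=30, seed=5)
        res = run_unconditional(cfg)
        assert res.v_true == pytest.approx(0.0)
        pop = make_population(200, 20, 0.0, "linear", rng=np.random.default_rng(
            np.random.SeedSequence(5).spawn(2)[0]
        ))
        closed = collapsed_bias_exact(pop.stratum_totals, make_pairing(20))
        bias = res.metrics.set_index("estimator").loc["collapsed", "bias"]
        assert bias == pytest.approx(closed, rel=1e-10)

    def test_partial_collapsing_option(self):
        cfg = SimulationConfig(
            N=200, H=20, sigma=0.25, h=0.06, R=5, B=30, seed=6, n_collapsed=10
        )
        res = run_unconditional(cfg)
        assert np.isfinite(res.metrics["bias"]).all()


class TestConditional:
    def test_group_structure_and_pooling(self):
        cfg = SimulationConfig(
            N=300, H=30, sigma=0.25, h=0.05, R=100, B=20, seed=7, n_groups=10
        )
        res = run_conditional(cfg)
        cond = res.conditional
        assert cond["group"].nunique() == 10
        # group means of xbar nondecreasing (forced by sorting)
        xbars = cond.groupby("group")["xbar"].first().to_numpy()
        assert np.all(np.diff(xbars) >= -1e-15)
        # pooled conditional biases reproduce the unconditional bias
        for est in ("collapsed", "kernel", "bootstrap"):
            pooled = cond[cond["estimator"] == est]["bias"].mean()
            uncond = res.metrics.set_index("estimator").loc[est, "bias"]
            assert pooled == pytest.approx(uncond, abs=1e-10)

    def test_indivisible_group_count_rejected(self):
        with pytest.raises(ConfigError):
            run_conditional(
                SimulationConfig(N=300, H=30, sigma=0.25, h=0.05, R=101, B=10, n_groups=10)
            )


class TestConfigValidation:
    def test_indivisible_population_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(N=1000, H=30)

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(N=3000, H=100, h=0.0)

    def test_unknown_mean_function_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(mean_fn="sigmoid")

    def test_tidy_export_shape(self):
        cfg = SimulationConfig(N=200, H=20, sigma=0.25, h=0.06, R=3, B=10, seed=8)
        res = run_unconditional(cfg)
        tidy = res.to_tidy()
        assert set(tidy.columns) == {"H", "h", "sigma", "mean_fn", "estimator", "metric", "value"}
        assert len(tidy) == 3 * 3  # three estimators x three metrics
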