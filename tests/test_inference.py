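"""Posterior engines and grid prediction."""

import numpy as np
import pytest

from gridvax.geometry import (
    ArealCounts,
    CovariateStack,
    build_grid,
    build_unit_square_partition,
    assign_membership,
    median_pairwise_distance,
)
from gridvax.inference import credible_interval, fit, predict
from gridvax.model import PriorSpec

TOY_CONTROLS = {"max_edge": 0.12}


@pytest.fixture(scope="module")
def toy_fit(strip_toy):
    f = fit(
        strip_toy["counts"],
        strip_toy["cov"],
        strip_toy["partition"],
        strip_toy["grid"],
        priors=strip_toy["priors"],
        engine="laplace",
        seed=3,
        controls=TOY_CONTROLS,
    )
    return f


class TestLaplaceEngine:
    def test_summary_schema(self, toy_fit):
        df = toy_fit.theta_summary
        assert list(df.columns) == ["parameter", "mean", "sd", "q2.5", "q97.5"]
        names = set(df["parameter"])
        assert {"beta_0", "beta_1", "sigma2_eta", "kappa", "sigma2_phi", "rho", "range"} <= names
        assert np.all(df["q2.5"] <= df["q97.5"])
        assert np.all(np.isfinite(df[["mean", "sd"]].to_numpy()))

    def test_observed_area_estimates_track_empirical_proportions(self, strip_toy, toy_fit):
        pred = predict(toy_fit, strip_toy["cov"], strip_toy["grid"], strip_toy["membership"])
        emp = strip_toy["counts"].Y / strip_toy["counts"].N
        assert np.max(np.abs(pred.area_estimates - emp)) < 0.05

    def test_prediction_bounds_and_order(self, strip_toy, toy_fit):
        pred = predict(toy_fit, strip_toy["cov"], strip_toy["grid"], strip_toy["membership"])
        assert np.all((pred.lower95 >= 0) & (pred.upper95 <= 1))
        assert np.all(pred.lower95 <= pred.mean + 1e-9)
        assert np.all(pred.mean <= pred.upper95 + 1e-9)
        assert np.all(pred.sd >= 0)

    def test_binomial_intercept_limit(self):
        # one area, intercept only, spatial variances pinned to ~0: the
        # posterior mean of p approaches the empirical proportion
        part = build_unit_square_partition(1)
        grid = build_grid(6, 6, (0, 0, 1, 1))
        mem = assign_membership(grid, part)
        cov = CovariateStack(np.ones((36, 1)), np.ones((1, 1)), ["i"])
        counts = ArealCounts(Y=np.array([700.0]), N=np.array([1000.0]))
        priors = PriorSpec().with_median_distance(median_pairwise_distance(grid, seed=0))
        f = fit(
            counts, cov, part, grid, priors=priors, engine="laplace", seed=0,
            controls={
                "max_edge": 0.3,
                "fix": {"sigma2_eta": 1e-8, "kappa": 8.0, "sigma2_phi": 1e-8, "rho": 0.5},
            },
        )
        pred = predict(f, cov, grid, mem)
        assert pred.area_estimates[0] == pytest.approx(0.7, abs=0.01)
        assert np.allclose(pred.mean, 0.7, atol=0.01)

    def test_missing_area_receives_estimate(self):
        part = build_unit_square_partition(2)
        grid = build_grid(10, 10, (0, 0, 1, 1))
        mem = assign_membership(grid, part)
        cov = CovariateStack(np.ones((100, 1)), np.ones((4, 1)), ["i"])
        counts = ArealCounts(
            Y=np.array([30.0, 40.0, 50.0, np.nan]), N=np.array([100.0, 100.0, 100.0, np.nan])
        )
        priors = PriorSpec().with_median_distance(median_pairwise_distance(grid, seed=0))
        f = fit(counts, cov, part, grid, priors=priors, seed=1, controls=TOY_CONTROLS)
        pred = predict(f, cov, grid, mem)
        assert np.isfinite(pred.area_estimates[3])
        assert 0.0 < pred.area_estimates[3] < 1.0
        # the unobserved area borrows strength: estimate within the observed range
        assert 0.2 < pred.area_estimates[3] < 0.6

    def test_nodata_covariate_cells_flagged(self, strip_toy, toy_fit):
        Xg = strip_toy["cov"].X_grid.copy()
        Xg[5, 1] = np.nan
        cov = CovariateStack(Xg, strip_toy["cov"].X_area, strip_toy["cov"].names)
        pred = predict(toy_fit, cov, strip_toy["grid"], strip_toy["membership"])
        assert not pred.valid[5] and np.isnan(pred.mean[5])
        assert np.isfinite(pred.mean[6])

    def test_unknown_control_key_rejected(self, strip_toy):
        with pytest.raises(ValueError, match="unknown control"):
            fit(
                strip_toy["counts"], strip_toy["cov"], strip_toy["partition"],
                strip_toy["grid"], engine="laplace", controls={"max_egde": 0.1},
            )


class TestObservedAreaTracking:
    def test_area_estimates_correlate_with_observed_proportions(self):
        # on a well-fit 100-area simulation the posterior areal estimates
        # track the observed proportions extremely closely (r > 0.97)
        from gridvax.simulation import SimSetting, _SettingCache, simulate_dataset

        setting = SimSetting(r=0.7, n_side=10, seed=12)
        cache = _SettingCache(setting)
        priors = PriorSpec().with_median_distance(
            median_pairwise_distance(cache.grid, seed=12)
        ).for_simulation_study()
        counts, cov, *_ = simulate_dataset(setting, 0, cache)
        f = fit(counts, cov, cache.partition, cache.grid, priors=priors, seed=12)
        pred = predict(f, cov, cache.grid, cache.membership)
        emp = counts.Y / counts.N
        assert np.corrcoef(pred.area_estimates, emp)[0, 1] > 0.97


class TestPermutationInvariance:
    def test_area_relabelling_leaves_predictions_unchanged(self):
        from gridvax.geometry import AreaPartition

        part = build_unit_square_partition(2)
        grid = build_grid(8, 8, (0, 0, 1, 1))
        mem = assign_membership(grid, part)
        rng = np.random.default_rng(11)
        Xa = np.column_stack([np.ones(4), rng.normal(size=4)])
        Xg = np.column_stack([np.ones(64), rng.normal(size=64)])
        cov = CovariateStack(Xg, Xa, ["i", "x"])
        counts = ArealCounts(Y=np.array([20.0, 40.0, 60.0, 80.0]), N=np.full(4, 100.0))
        priors = PriorSpec().with_median_distance(median_pairwise_distance(grid, seed=0))
        f = fit(counts, cov, part, grid, priors=priors, seed=5, controls=TOY_CONTROLS)
        pred = predict(f, cov, grid, mem)

        perm = np.array([2, 0, 3, 1])  # relabel areas
        inv = np.argsort(perm)
        part_p = AreaPartition(
            area_ids=[part.area_ids[i] for i in perm],
            polygons=[part.polygons[i] for i in perm],
            W=part.W[np.ix_(perm, perm)],
        )
        cov_p = CovariateStack(Xg, Xa[perm], ["i", "x"])
        counts_p = ArealCounts(Y=counts.Y[perm], N=counts.N[perm])
        grid_p = build_grid(8, 8, (0, 0, 1, 1))
        mem_p = assign_membership(grid_p, part_p)
        assert np.array_equal(inv[mem], mem_p)
        f_p = fit(counts_p, cov_p, part_p, grid_p, priors=priors, seed=5, controls=TOY_CONTROLS)
        pred_p = predict(f_p, cov_p, grid_p, mem_p)
        assert np.allclose(pred_p.mean, pred.mean, atol=5e-3)
        assert np.allclose(pred_p.area_estimates[inv[np.arange(4)]], pred.area_estimates, atol=5e-3)


class TestMCMCEngine:
    def test_engines_agree_on_toy(self, strip_toy, toy_fit):
        # the cross-engine oracle: Laplace vs MCMC posterior mean of grid p
        f_mcmc = fit(
            strip_toy["counts"], strip_toy["cov"], strip_toy["partition"], strip_toy["grid"],
            priors=strip_toy["priors"], engine="mcmc", seed=3,
            controls={"max_edge": 0.12, "chains": 2, "warmup": 300, "draws": 400},
        )
        p_l = predict(toy_fit, strip_toy["cov"], strip_toy["grid"], strip_toy["membership"])
        p_m = predict(f_mcmc, strip_toy["cov"], strip_toy["grid"], strip_toy["membership"])
        assert np.mean(np.abs(p_l.mean - p_m.mean)) < 0.03
        assert "rhat" in f_mcmc.diagnostics and "ess" in f_mcmc.diagnostics

    def test_seeded_reproducibility(self, strip_toy):
        kw = dict(
            priors=strip_toy["priors"], engine="mcmc", seed=9,
            controls={"max_edge": 0.15, "chains": 1, "warmup": 50, "draws": 50},
        )
        a = fit(strip_toy["counts"], strip_toy["cov"], strip_toy["partition"], strip_toy["grid"], **kw)
        b = fit(strip_toy["counts"], strip_toy["cov"], strip_toy["partition"], strip_toy["grid"], **kw)
        assert np.array_equal(a.latent_draws, b.latent_draws)


class TestCredibleInterval:
    def test_gaussian_pair(self):
        lo, hi = credible_interval((np.array([0.0]), np.array([1.0])), level=0.95)
        assert lo[0] == pytest.approx(-1.96, abs=0.001)
        assert hi[0] == pytest.approx(1.96, abs=0.001)

    def test_degenerate_posterior_collapses(self):
        lo, hi = credible_interval((np.array([0.3]), np.array([0.0])), level=0.95)
        assert lo[0] == hi[0] == pytest.approx(0.3)

    def test_normal_draws_large_sample(self):
        draws = np.random.default_rng(0).standard_normal(200_000)
        lo, hi = credible_interval(draws, level=0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_nested_levels(self):
        draws = np.random.default_rng(1).standard_normal(5000)
        lo50, hi50 = credible_interval(draws, level=0.5)
        lo95, hi95 = credible_interval(draws, level=0.95)
        assert lo95 < lo50 < hi50 < hi95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(np.array([]))
        with pytest.raises(ValueError):
            credible_interval(np.array([1.0]), level=1.5)
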