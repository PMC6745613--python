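"""Linear predictors, likelihood, priors and the joint posterior."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom, gamma as gamma_dist, norm

from gridvax.geometry import ArealCounts, CovariateStack
from gridvax.latent import LerouxParams, MaternParams, leroux_precision
from gridvax.model import (
    ModelParams,
    PriorSpec,
    binomial_loglik,
    cluster_model_logposterior,
    gmrf_logpdf,
    linear_predictor_area,
    linear_predictor_grid,
    log_posterior,
    log_prior,
)


def _toy_cov(k=1, nA=2, n_grid=4):
    Xg = np.ones((n_grid, k))
    Xa = np.ones((nA, k))
    return CovariateStack(Xg, Xa, [f"x{j}" for j in range(k)])


class TestLinearPredictors:
    def test_all_zero_gives_half(self):
        cov = _toy_cov()
        params = ModelParams(beta=np.zeros(1))
        la = linear_predictor_area(params, cov, np.zeros(2), np.zeros(2))
        assert np.allclose(expit(la), 0.5)
        lg = linear_predictor_grid(params, cov, np.zeros(4), np.zeros(2), np.zeros(4, int))
        assert np.allclose(expit(lg), 0.5)

    def test_hand_sum_cancels_to_half(self):
        cov = _toy_cov()
        params = ModelParams(beta=np.array([0.2]))
        la = linear_predictor_area(params, cov, np.full(2, 0.1), np.full(2, -0.3))
        assert np.allclose(la, 0.0)
        assert np.allclose(expit(la), 0.5)

    def test_grid_cells_share_area_phi(self):
        cov = CovariateStack(
            np.array([[1.0, 0.5], [1.0, 2.0]]), np.ones((1, 2)), ["i", "x"]
        )
        params = ModelParams(beta=np.array([0.1, 0.3]))
        lg = linear_predictor_grid(
            params, cov, np.array([0.0, 0.0]), np.array([0.7]), np.array([0, 0])
        )
        # difference comes only from x'beta, phi is common
        assert lg[1] - lg[0] == pytest.approx(0.3 * 1.5)
        assert lg[0] == pytest.approx(0.1 + 0.15 + 0.7)

    def test_constant_eta_matches_between_supports(self):
        # block-averaging exactness: constant eta and covariates within an
        # area give identical area- and grid-level logits
        cov = _toy_cov(k=1, nA=1, n_grid=3)
        params = ModelParams(beta=np.array([0.4]))
        eta_c = 0.25
        la = linear_predictor_area(params, cov, np.array([eta_c]), np.array([-0.1]))
        lg = linear_predictor_grid(
            params, cov, np.full(3, eta_c), np.array([-0.1]), np.zeros(3, int)
        )
        assert np.allclose(lg, la[0])

    def test_outside_cells_use_zero_phi(self):
        cov = _toy_cov(n_grid=2)
        params = ModelParams(beta=np.zeros(1))
        lg = linear_predictor_grid(
            params, cov, np.zeros(2), np.array([5.0, 5.0]), np.array([0, -1])
        )
        assert lg[0] == pytest.approx(5.0) and lg[1] == pytest.approx(0.0)

    def test_dimension_mismatch(self):
        cov = _toy_cov()
        with pytest.raises(ValueError):
            linear_predictor_area(ModelParams(beta=np.zeros(2)), cov, np.zeros(2), np.zeros(2))


class TestBinomialLoglik:
    def test_certain_success_is_zero(self):
        assert binomial_loglik([5], [5], [1.0 - 1e-13]) == pytest.approx(0.0, abs=1e-9)

    def test_hand_case_matches_scipy_oracle(self):
        assert binomial_loglik([1], [2], [0.5]) == pytest.approx(np.log(0.5))
        rng = np.random.default_rng(1)
        N = rng.integers(1, 50, 10)
        Y = rng.binomial(N, 0.4)
        p = rng.uniform(0.1, 0.9, 10)
        assert binomial_loglik(Y, N, p) == pytest.approx(binom.logpmf(Y, N, p).sum())

    def test_masked_area_contributes_nothing(self):
        full = binomial_loglik([3, 7], [10, 10], [0.3, 0.7], mask=[True, True])
        part = binomial_loglik([3, 7], [10, 10], [0.3, 0.7], mask=[True, False])
        assert part == pytest.approx(binomial_loglik([3], [10], [0.3]))
        assert part != full

    def test_y_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_loglik([3], [2], [0.5])


class TestPriors:
    def test_beta_term_at_zero(self):
        priors = PriorSpec()
        params = ModelParams(
            beta=np.zeros(3),
            matern=MaternParams(sigma2_eta=1.0, kappa=8.0),
            leroux=LerouxParams(sigma2_phi=1.0, rho=0.5),
        )
        lp = log_prior(params, priors)
        # subtract everything except the beta block by re-evaluating with k=0
        lp0 = log_prior(
            ModelParams(beta=np.zeros(0), matern=params.matern, leroux=params.leroux), priors
        )
        assert lp - lp0 == pytest.approx(3 * norm.logpdf(0.0, 0.0, np.sqrt(1e5)))

    def test_car_precision_term_matches_gamma_oracle(self):
        priors = PriorSpec(car_prec_gamma=(5.0, 1.0))
        base = ModelParams(beta=np.zeros(0), leroux=LerouxParams(sigma2_phi=1.0, rho=0.5))
        other = ModelParams(beta=np.zeros(0), leroux=LerouxParams(sigma2_phi=0.25, rho=0.5))
        diff = log_prior(other, priors) - log_prior(base, priors)
        oracle = gamma_dist.logpdf(4.0, a=5.0, scale=1.0) - gamma_dist.logpdf(
            1.0, a=5.0, scale=1.0
        )
        assert diff == pytest.approx(oracle)

    def test_rho_half_is_logit_normal_mode(self):
        priors = PriorSpec(rho_logit_normal=(0.0, 0.45))
        mk = lambda rho: ModelParams(beta=np.zeros(0), leroux=LerouxParams(rho=rho))
        assert log_prior(mk(0.5), priors) > log_prior(mk(0.9), priors)
        # the logit-rho density term at rho=0.5 equals the N(0, 0.45) density at 0
        diff = log_prior(mk(0.5), priors) - log_prior(mk(0.731058578), priors)
        oracle = norm.logpdf(0.0, 0.0, np.sqrt(0.45)) - norm.logpdf(1.0, 0.0, np.sqrt(0.45))
        assert diff == pytest.approx(oracle, abs=1e-6)

    def test_kappa_at_prior_mean_beats_neighbours(self):
        priors = PriorSpec(kappa_lognormal_mean=np.log(8.0), log_tau_normal=(0.0, 1e8))
        mk = lambda kap: ModelParams(beta=np.zeros(0), matern=MaternParams(kappa=kap))
        assert log_prior(mk(8.0), priors) > log_prior(mk(16.0), priors)
        assert log_prior(mk(8.0), priors) > log_prior(mk(4.0), priors)

    def test_out_of_support_is_minus_inf(self):
        priors = PriorSpec()
        bad = ModelParams(beta=np.zeros(1), leroux=LerouxParams(sigma2_phi=1.0, rho=0.0))
        assert log_prior(bad, priors) == -np.inf


class TestJointPosterior:
    def _setup(self, nA=2, seed=0):
        rng = np.random.default_rng(seed)
        W = np.zeros((nA, nA))
        for i in range(nA - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
        cov = CovariateStack(np.ones((4, 1)), np.ones((nA, 1)), ["i"])
        counts = ArealCounts(Y=np.array([30.0, 45.0][:nA]), N=np.array([60.0, 60.0][:nA]))
        Q_eta = np.eye(nA) * 2.0
        eta_w = rng.normal(size=nA) * 0.1
        phi = rng.normal(size=nA) * 0.1
        params = ModelParams(beta=np.array([0.1]))
        return params, eta_w, phi, counts, cov, Q_eta, W

    def test_additivity_of_components(self):
        params, eta_w, phi, counts, cov, Q_eta, W = self._setup()
        priors = PriorSpec()
        lp = log_posterior(params, eta_w, phi, counts, cov, Q_eta, eta_w, W, priors)
        logits = cov.X_area @ params.beta + eta_w + phi
        expected = (
            binomial_loglik(counts.Y, counts.N, expit(logits))
            + gmrf_logpdf(eta_w, Q_eta)
            + gmrf_logpdf(phi, leroux_precision(W, params.leroux.rho) / params.leroux.sigma2_phi)
            + log_prior(params, priors)
        )
        assert lp == pytest.approx(expected)

    def test_likelihood_curvature_around_fitted_proportion(self):
        # moving Y away from N * p lowers the posterior, all else fixed
        params, eta_w, phi, counts, cov, Q_eta, W = self._setup()
        priors = PriorSpec()
        p = expit(cov.X_area @ params.beta + eta_w + phi)
        best_y = np.round(counts.N * p)
        vals = []
        for shift in (0.0, 5.0, 15.0):
            counts_s = ArealCounts(Y=best_y + shift, N=counts.N)
            vals.append(
                log_posterior(params, eta_w, phi, counts_s, cov, Q_eta, eta_w, W, priors)
            )
        assert vals[0] > vals[1] > vals[2]

    def test_permutation_invariance(self):
        params, eta_w, phi, counts, cov, Q_eta, W = self._setup()
        priors = PriorSpec()
        lp = log_posterior(params, eta_w, phi, counts, cov, Q_eta, eta_w, W, priors)
        perm = np.array([1, 0])
        counts_p = ArealCounts(Y=counts.Y[perm], N=counts.N[perm])
        lp_p = log_posterior(
            params,
            eta_w[perm],
            phi[perm],
            counts_p,
            cov,
            Q_eta[np.ix_(perm, perm)],
            eta_w[perm],
            W[np.ix_(perm, perm)],
            priors,
        )
        assert lp == pytest.approx(lp_p)


def _car_related_prior_terms(params, priors):
    """Gamma(CAR precision) + logit-rho density terms, computed by hand."""
    from scipy.special import gammaln

    shape, rate = priors.car_prec_gamma
    prec = 1.0 / params.leroux.sigma2_phi
    gam = shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(prec) - rate * prec
    mean, var = priors.rho_logit_normal
    rho = params.leroux.rho
    lr = norm.logpdf(np.log(rho / (1 - rho)), mean, np.sqrt(var))
    return float(gam + lr)


class TestClusterModel:
    def test_zero_gp_beta_gives_half(self):
        priors = PriorSpec()
        params = ModelParams(beta=np.zeros(1))
        lp = cluster_model_logposterior(
            params,
            cluster_Y=np.array([1.0]),
            cluster_N=np.array([2.0]),
            X_cluster=np.ones((1, 1)),
            eta_weights=np.zeros(2),
            eta_cluster=np.zeros(1),
            eta_precision=np.eye(2),
            priors=priors,
        )
        # binomial part: log C(2,1) + 2 log 0.5 = log 0.5; prior parts are
        # the full areal-model prior minus its CAR-related terms
        expected = (
            np.log(0.5)
            + gmrf_logpdf(np.zeros(2), np.eye(2))
            + log_prior(params, priors)
            - _car_related_prior_terms(params, priors)
        )
        assert lp == pytest.approx(expected)

    def test_matches_areal_model_minus_car_on_degenerate_layout(self):
        # one cluster per area at its centroid, phi = 0: the cluster model's
        # posterior equals the areal model's minus the CAR density and the
        # CAR-related prior terms
        nA = 3
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(nA, 2))
        cov = CovariateStack(X, X, ["a", "b"])
        counts = ArealCounts(Y=np.array([10.0, 20.0, 30.0]), N=np.array([40.0, 40.0, 40.0]))
        Q_eta = np.eye(nA) * 3.0
        eta = rng.normal(size=nA) * 0.2
        phi = np.zeros(nA)
        params = ModelParams(beta=np.array([0.3, -0.1]))
        priors = PriorSpec()
        lp_area = log_posterior(params, eta, phi, counts, cov, Q_eta, eta, W, priors)
        lp_clus = cluster_model_logposterior(
            params, counts.Y, counts.N, X, eta, eta, Q_eta, priors
        )
        car_density = gmrf_logpdf(
            phi, leroux_precision(W, params.leroux.rho) / params.leroux.sigma2_phi
        )
        assert lp_area - lp_clus == pytest.approx(
            car_density + _car_related_prior_terms(params, priors)
        )
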