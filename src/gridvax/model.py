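"""Joint disaggregation model: linear predictors, likelihood, priors, posterior.

The model links areal counts to the prediction grid through one set of
regression coefficients and the two latent fields::

    Y_i ~ Binomial(N_i, p_i)                       observed areas only
    logit(p_i) = x~_i' beta + mean_{A_i}(eta) + phi_i        (areal support)
    logit(p_s) = x_s' beta + eta(s) + phi_{A(s)}             (grid support)

Grid-level counts are never observed — the grid equations exist purely to
define the prediction targets p(s), which the shared coefficients and the
block-averaged latent GP tie back to the data.

Priors follow standard latent-Gaussian practice: a flat-ish Gaussian on beta,
a Gamma prior on the CAR precision, a logit-normal on the CAR mixing
parameter rho, and a log-normal on kappa centred at log(8/m) with m the
median inter-grid distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, gammaln

from .geometry import ArealCounts, CovariateStack
from .latent import LerouxParams, MaternParams, leroux_precision

__all__ = [
    "ModelParams",
    "PriorSpec",
    "linear_predictor_area",
    "linear_predictor_grid",
    "binomial_loglik",
    "log_prior",
    "log_posterior",
    "cluster_model_logposterior",
    "P_CLIP",
]

P_CLIP = 1e-12  # probabilities clipped to [P_CLIP, 1 - P_CLIP] before logs


@dataclass
class ModelParams:
    """Full parameter vector theta = (beta, sigma2_eta, kappa, sigma2_phi, rho)."""

    beta: np.ndarray
    matern: MaternParams = field(default_factory=MaternParams)
    leroux: LerouxParams = field(default_factory=LerouxParams)

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))


@dataclass
class PriorSpec:
    """Hyperparameters of the prior distributions.

    * ``beta_var`` — variance of the independent N(0, beta_var) priors on all
      regression coefficients, intercept included (default 1e5).
    * ``car_prec_gamma`` — (shape, rate) of the Gamma prior on the CAR
      precision 1/sigma2_phi.  Default (1, 0.01); simulation-study mode uses
      (5, 1).
    * ``rho_logit_normal`` — (mean, variance) of the normal prior on
      logit(rho).  NOTE: the 0.45 default is interpreted as a VARIANCE
      (sd = sqrt(0.45) ~ 0.67); set the second entry accordingly if your
      convention differs.
    * ``kappa_lognormal_mean`` — mean of the N(., 1) prior on log kappa;
      the standard choice is log(8 / m) with m the median distance between
      prediction grid points (set via :meth:`with_median_distance`).
    * ``log_tau_normal`` — (mean, variance) of the normal prior on the log
      SPDE precision scale log tau (tau^2 = 1 / (4 pi kappa^2 sigma2_eta)),
      the default prior on the GP variance.  The variance must be large to
      be genuinely non-informative: var-1 on log tau would concentrate
      sigma2_eta near 4 pi / kappa^2 e^{...}, i.e. near zero for short
      ranges, and empirically collapses the GP.  Default (0, 10), the usual
      vague Gaussian (precision 0.1) of SPDE practice.
    """

    beta_var: float = 1e5
    car_prec_gamma: tuple = (1.0, 0.01)
    rho_logit_normal: tuple = (0.0, 0.45)
    kappa_lognormal_mean: float = np.log(8.0)
    kappa_lognormal_var: float = 1.0
    log_tau_normal: tuple = (0.0, 10.0)

    def with_median_distance(self, m: float) -> "PriorSpec":
        """Centre the log-kappa prior at log(8 / m)."""
        return replace(self, kappa_lognormal_mean=float(np.log(8.0 / m)))

    def for_simulation_study(self) -> "PriorSpec":
        """Swap in the Gamma(5, 1) CAR-precision prior used in study mode."""
        return replace(self, car_prec_gamma=(5.0, 1.0))


# ---------------------------------------------------------------------------
# Linear predictors and likelihood
# ---------------------------------------------------------------------------


def linear_predictor_area(
    params: ModelParams, cov: CovariateStack, eta_area: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Areal-support logits: x~_i' beta + area-averaged eta + phi_i."""
    eta_area = np.asarray(eta_area, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if cov.X_area.shape[1] != len(params.beta):
        raise ValueError("beta length does not match the covariate stack")
    if not (cov.X_area.shape[0] == len(eta_area) == len(phi)):
        raise ValueError("area-level dimension mismatch")
    return cov.X_area @ params.beta + eta_area + phi


def linear_predictor_grid(
    params: ModelParams,
    cov: CovariateStack,
    eta: np.ndarray,
    phi: np.ndarray,
    membership: np.ndarray,
) -> np.ndarray:
    """Grid-support logits: x_s' beta + eta(s) + phi of the containing area.

    Cells outside the partition (membership -1) take phi = 0; they are
    flagged by the caller and excluded from any likelihood, so the value
    only affects exploratory prediction outside the mapped domain.
    """
    eta = np.asarray(eta, dtype=float)
    membership = np.asarray(membership, dtype=int)
    phi = np.asarray(phi, dtype=float)
    if cov.X_grid.shape[1] != len(params.beta):
        raise ValueError("beta length does not match the covariate stack")
    if not (cov.X_grid.shape[0] == len(eta) == len(membership)):
        raise ValueError("grid-level dimension mismatch")
    phi_cell = np.where(membership >= 0, phi[np.clip(membership, 0, None)], 0.0)
    return cov.X_grid @ params.beta + eta + phi_cell


def binomial_loglik(Y, N, p, mask=None) -> float:
    """Binomial log likelihood over observed units, with masked units skipped.

    Probabilities are clipped to [1e-12, 1 - 1e-12] for numeric safety; the
    combinatorial term is included so values match ``scipy.stats.binom``.
    """
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    N = np.atleast_1d(np.asarray(N, dtype=float))
    p = np.clip(np.atleast_1d(np.asarray(p, dtype=float)), P_CLIP, 1.0 - P_CLIP)
    if mask is None:
        mask = np.ones_like(Y, dtype=bool)
    mask = np.atleast_1d(np.asarray(mask, dtype=bool))
    Y, N, p = Y[mask], N[mask], p[mask]
    if np.any(Y > N) or np.any(Y < 0):
        raise ValueError("need 0 <= Y <= N")
    ll = (
        gammaln(N + 1.0)
        - gammaln(Y + 1.0)
        - gammaln(N - Y + 1.0)
        + Y * np.log(p)
        + (N - Y) * np.log1p(-p)
    )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Priors and joint posterior
# ---------------------------------------------------------------------------


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def log_prior(params: ModelParams, priors: PriorSpec) -> float:
    """Joint log prior density of theta, on the natural parameter scale.

    Densities are specified on transformed scales (Gamma on the CAR
    precision, normal on logit rho and on log kappa and log tau); the
    Jacobians of those transforms are NOT included here — they belong to
    whichever sampler or optimizer works on the transformed coordinates.
    Out-of-support parameters return -inf.
    """
    m = params.matern
    l = params.leroux
    if m.sigma2_eta <= 0 or m.kappa <= 0 or l.sigma2_phi <= 0:
        return -np.inf
    if not (0.0 < l.rho < 1.0):
        return -np.inf
    lp = float(np.sum(_norm_logpdf(params.beta, 0.0, priors.beta_var)))
    # Gamma(shape, rate) on the CAR precision
    shape, rate = priors.car_prec_gamma
    prec = 1.0 / l.sigma2_phi
    lp += shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(prec) - rate * prec
    # normal on logit rho
    mean, var = priors.rho_logit_normal
    lp += float(_norm_logpdf(np.log(l.rho / (1.0 - l.rho)), mean, var))
    # log-normal on kappa
    lp += float(
        _norm_logpdf(np.log(m.kappa), priors.kappa_lognormal_mean, priors.kappa_lognormal_var)
    )
    # vague normal on log tau (SPDE scale), the default prior on sigma2_eta
    log_tau = -0.5 * np.log(4.0 * np.pi) - np.log(m.kappa) - 0.5 * np.log(m.sigma2_eta)
    mean, var = priors.log_tau_normal
    lp += float(_norm_logpdf(log_tau, mean, var))
    return lp


def gmrf_logpdf(x: np.ndarray, Q, logdet_Q: float = None) -> float:
    """Log density of a zero-mean Gaussian with precision Q (dense or sparse)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if logdet_Q is None:
        Qd = Q.toarray() if hasattr(Q, "toarray") else np.asarray(Q)
        sign, logdet_Q = np.linalg.slogdet(Qd)
        if sign <= 0:
            return -np.inf
    quad = float(x @ (Q @ x))
    return 0.5 * (logdet_Q - n * np.log(2.0 * np.pi) - quad)


def log_posterior(
    params: ModelParams,
    eta_weights: np.ndarray,
    phi: np.ndarray,
    data: ArealCounts,
    cov: CovariateStack,
    eta_precision,
    eta_area: np.ndarray,
    W: np.ndarray,
    priors: PriorSpec,
) -> float:
    """Joint log posterior (up to a constant) of (theta, eta, phi).

    ``eta_weights`` are the GP values in whichever representation is in use
    (grid values with a dense precision, or mesh-vertex weights with the
    sparse SPDE precision); ``eta_area`` is their area average under the same
    representation, supplied by the caller so both dense and SPDE routes use
    one code path.  The value is the sum of the binomial likelihood over
    observed areas, the GMRF density of eta, the CAR density of phi and the
    parameter prior.
    """
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    logits = linear_predictor_area(params, cov, eta_area, phi)
    p = expit(logits)
    ll = binomial_loglik(data.Y, data.N, p, mask=data.observed)
    lg = gmrf_logpdf(eta_weights, eta_precision)
    Q_phi = leroux_precision_scaled(params, W)
    lc = gmrf_logpdf(phi, Q_phi)
    return float(ll + lg + lc + lp)


def leroux_precision_scaled(params: ModelParams, W: np.ndarray) -> np.ndarray:
    """CAR precision including the variance scale: Q(W) / sigma2_phi."""
    return leroux_precision(W, params.leroux.rho) / params.leroux.sigma2_phi


def cluster_model_logposterior(
    params: ModelParams,
    cluster_Y: np.ndarray,
    cluster_N: np.ndarray,
    X_cluster: np.ndarray,
    eta_weights: np.ndarray,
    eta_cluster: np.ndarray,
    eta_precision,
    priors: PriorSpec,
) -> float:
    """Log posterior of the cluster-to-grid variant (no areal CAR effect).

    For geolocated cluster data the areal random effect is dropped and the
    GP is evaluated at the n_c cluster coordinates:
    ``logit(p_i) = x_i' beta + eta(s_i)``.  The rho / sigma2_phi entries of
    ``params`` are ignored, as is their prior.
    """
    m = params.matern
    if m.sigma2_eta <= 0 or m.kappa <= 0:
        return -np.inf
    lp = float(np.sum(_norm_logpdf(params.beta, 0.0, priors.beta_var)))
    lp += float(
        _norm_logpdf(np.log(m.kappa), priors.kappa_lognormal_mean, priors.kappa_lognormal_var)
    )
    log_tau = -0.5 * np.log(4.0 * np.pi) - np.log(m.kappa) - 0.5 * np.log(m.sigma2_eta)
    mean, var = priors.log_tau_normal
    lp += float(_norm_logpdf(log_tau, mean, var))
    X_cluster = np.atleast_2d(X_cluster)
    logits = X_cluster @ params.beta + np.asarray(eta_cluster, dtype=float)
    ll = binomial_loglik(cluster_Y, cluster_N, expit(logits))
    lg = gmrf_logpdf(eta_weights, eta_precision)
    return float(ll + lg + lp)
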