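"""Posterior computation and grid prediction.

The model is a latent Gaussian model: conditional on the hyperparameters
``theta = (sigma2_eta, kappa, sigma2_phi, rho)`` the latent vector
``z = (beta, eta~, phi)`` is Gaussian with a sparse block precision, and the
data enter through a binomial likelihood at the observed areas only (grid
counts are never observed).  Two interchangeable engines exploit this:

* ``laplace`` (default) — empirical-Bayes Laplace approximation: an inner
  Newton iteration finds the conditional mode of ``z`` and its Gaussian
  (Laplace) approximation; an outer derivative-free optimizer maximizes the
  Laplace-approximated log posterior of ``theta`` on transformed scales;
  hyperparameter uncertainty comes from a finite-difference Hessian at the
  mode.  This mirrors what fast deterministic fitters for latent Gaussian
  models do, without reimplementing any of them.
* ``mcmc`` — an exact sampler used as the independent cross-check:
  random-walk Metropolis on ``theta`` alternating with Laplace independence
  proposals for the latent block, multiple seeded chains, split-Rhat and
  effective-sample-size diagnostics.

Both engines emit the same summary schema, and a cross-engine agreement test
is the primary correctness surface: the approximate engine is validated
against the exact sampler rather than against any external fitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular, LinAlgError
from scipy.optimize import minimize
from scipy.special import expit, roots_hermitenorm

from .geometry import (
    AreaPartition,
    ArealCounts,
    CovariateStack,
    GridDomain,
    median_pairwise_distance,
)
from .latent import (
    LerouxParams,
    MaternParams,
    Mesh,
    build_mesh,
    leroux_precision,
    point_projector,
    spde_precision,
)
from .model import ModelParams, PriorSpec, P_CLIP, binomial_loglik

logger = logging.getLogger("gridvax")

__all__ = ["PosteriorFit", "GridPrediction", "fit", "predict", "credible_interval"]

_THETA_NAMES = ("sigma2_eta", "kappa", "sigma2_phi", "rho")

# default engine controls; overridable through the ``controls`` dict of fit()
DEFAULT_CONTROLS = {
    "max_edge": None,  # mesh inner spacing; None -> domain diameter / 25
    "offset": None,  # buffer ring width; None -> 0.15 * diameter
    "mesh": None,  # prebuilt Mesh (skips construction)
    "inner_tol": 1e-6,  # relative tolerance of the latent Newton iteration
    "inner_maxiter": 50,
    "outer_tol": 1e-4,  # function tolerance of the hyperparameter optimizer
    "outer_maxiter": 100,
    "fix": None,  # dict pinning any of sigma2_eta/kappa/sigma2_phi/rho
    "theta_mix": True,  # integrate hyperparameters into Laplace predictions
    #                     (weighted axial design around the mode)
    "area_eta": "cells",  # area-average the GP over grid cells ('cells') or
    #                       mesh vertices ('vertices', the 1/V_i rule)
    "chains": 4,  # MCMC
    "warmup": 1000,
    "draws": 1000,
    "rhat_warn": 1.05,
}


@dataclass
class PosteriorFit:
    """Posterior of the hyperparameters plus a joint latent representation.

    ``latent_mean``/``latent_chol_H`` hold the Gaussian (Laplace)
    approximation N(mean, H^-1) of ``z = (beta, eta~, phi)`` at the
    hyperparameter mode; the MCMC engine additionally stores latent and
    hyperparameter draws.  Either representation suffices to predict any
    ``p_i``.
    """

    engine: str
    theta_summary: pd.DataFrame
    theta_mode: ModelParams
    latent_mean: np.ndarray
    latent_chol_H: tuple  # cho_factor of the latent posterior precision
    mesh: Mesh
    partition: AreaPartition
    k: int
    diagnostics: dict = field(default_factory=dict)
    latent_draws: np.ndarray = None  # (S, dim) for the mcmc engine
    mixture: list = None  # [(z_hat, cho_H, weight), ...] over theta design points
    A_area_eta: sp.csr_matrix = None  # area-averaging projector used in the fit
    seed: int = 0

    @property
    def beta_mean(self) -> np.ndarray:
        return self.latent_mean[: self.k]

    def summary_csv(self, path):
        """Export the parameter summary as CSV (parameter, mean, sd, q2.5, q97.5)."""
        self.theta_summary.to_csv(path, index=False)


@dataclass
class GridPrediction:
    """Per-cell posterior mean, SD and equal-tailed 95% interval of p(s)."""

    mean: np.ndarray
    sd: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    area_estimates: np.ndarray  # posterior mean of areal p, missing areas included
    area_lower95: np.ndarray = None
    area_upper95: np.ndarray = None
    valid: np.ndarray = None  # False where covariate nodata forced exclusion

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.mean)

    def to_frame(self, points: np.ndarray = None) -> pd.DataFrame:
        cols = {
            "mean": self.mean,
            "sd": self.sd,
            "lower95": self.lower95,
            "upper95": self.upper95,
        }
        df = pd.DataFrame(cols)
        if points is not None:
            df.insert(0, "y", points[:, 1])
            df.insert(0, "x", points[:, 0])
        return df


# ---------------------------------------------------------------------------
# Transformed hyperparameter scale
# ---------------------------------------------------------------------------
# Working coordinates: x = (log sigma2_eta, log kappa, log precision_phi,
# logit rho) — the scales the priors are stated on, which also keeps the
# optimizer unconstrained.


def _theta_to_x(theta: ModelParams) -> np.ndarray:
    return np.array(
        [
            np.log(theta.matern.sigma2_eta),
            np.log(theta.matern.kappa),
            -np.log(theta.leroux.sigma2_phi),
            np.log(theta.leroux.rho / (1.0 - theta.leroux.rho)),
        ]
    )


def _x_to_theta(x: np.ndarray, beta: np.ndarray = None) -> ModelParams:
    return ModelParams(
        beta=np.zeros(1) if beta is None else beta,
        matern=MaternParams(sigma2_eta=float(np.exp(x[0])), kappa=float(np.exp(x[1]))),
        leroux=LerouxParams(sigma2_phi=float(np.exp(-x[2])), rho=float(expit(x[3]))),
    )


def _log_prior_x(x: np.ndarray, priors: PriorSpec) -> float:
    """Log prior density in the working coordinates (Jacobians included)."""

    def norm(v, mean, var):
        return -0.5 * (np.log(2.0 * np.pi * var) + (v - mean) ** 2 / var)

    log_s2, log_kap, log_prec, logit_rho = x
    shape, rate = priors.car_prec_gamma
    # Gamma density on the precision, plus the log-scale Jacobian exp(log_prec)
    lp = shape * np.log(rate) + shape * log_prec - rate * np.exp(log_prec)
    mean, var = priors.rho_logit_normal
    lp += norm(logit_rho, mean, var)
    lp += norm(log_kap, priors.kappa_lognormal_mean, priors.kappa_lognormal_var)
    log_tau = -0.5 * np.log(4.0 * np.pi) - log_kap - 0.5 * log_s2
    mean, var = priors.log_tau_normal
    lp += norm(log_tau, mean, var)
    return float(lp)


# ---------------------------------------------------------------------------
# Model workspace: fixed matrices shared by both engines
# ---------------------------------------------------------------------------


class _Workspace:
    """Precomputed structures: projectors, design blocks, index slices."""

    def __init__(self, data, cov, partition, grid, priors, controls, seed):
        self.data = data
        self.cov = cov
        self.partition = partition
        self.grid = grid
        self.priors = priors
        self.controls = controls
        self.seed = seed
        mesh = controls["mesh"]
        if mesh is None:
            mesh = build_mesh(
                partition=partition,
                max_edge=controls["max_edge"],
                offset=controls["offset"],
                points=grid.points,
            )
        elif mesh.A_points is None or mesh.A_areas is None:
            raise ValueError("a prebuilt mesh must carry A_points and A_areas")
        self.mesh = mesh
        self.k = cov.k
        self.G = mesh.n_vertices
        self.nA = partition.n_areas
        self.dim = self.k + self.G + self.nA
        self.sl_beta = slice(0, self.k)
        self.sl_eta = slice(self.k, self.k + self.G)
        self.sl_phi = slice(self.k + self.G, self.dim)
        # area-averaging of the GP: either the mean over the grid cells in
        # each area (exact counterpart of the block-average definition) or
        # the coarser 1/V_i mesh-vertex rule
        if controls["area_eta"] == "cells" and grid.membership is not None:
            member = grid.membership
            inside = member >= 0
            counts = np.bincount(member[inside], minlength=self.nA)
            rows = member[inside]
            Mavg = sp.csr_matrix(
                (1.0 / counts[rows], (rows, np.flatnonzero(inside))),
                shape=(partition.n_areas, grid.n_points),
            )
            self.A_area_eta = (Mavg @ mesh.A_points).tocsr()
        else:
            self.A_area_eta = mesh.A_areas
        # observation design: logits_area = B_obs @ z
        self.B_area = np.hstack(
            [cov.X_area, self.A_area_eta.toarray(), np.eye(partition.n_areas)]
        )
        self.obs = data.observed
        self.Bo = self.B_area[self.obs]
        self.Yo = data.Y[self.obs]
        self.No = data.N[self.obs]
        self.W = partition.W

    def prior_blocks(self, x):
        """(Q_eta sparse, Q_phi dense, logdet of the full latent prior precision)."""
        theta = _x_to_theta(x)
        Q_eta = spde_precision(self.mesh, theta.matern)
        prec_phi = np.exp(x[2])
        Q_rho = leroux_precision(self.W, theta.leroux.rho)
        sign, logdet_rho = np.linalg.slogdet(Q_rho)
        Q_phi = prec_phi * Q_rho
        logdet_eta = _sparse_logdet(Q_eta)
        logdet = (
            -self.k * np.log(self.priors.beta_var)
            + logdet_eta
            + self.nA * np.log(prec_phi)
            + logdet_rho
        )
        return Q_eta, Q_phi, float(logdet)

    def q_quad(self, z, Q_eta, Q_phi):
        """Quadratic form z' Q_z z of the latent prior."""
        b = z[self.sl_beta]
        e = z[self.sl_eta]
        f = z[self.sl_phi]
        return float(b @ b / self.priors.beta_var + e @ (Q_eta @ e) + f @ (Q_phi @ f))

    def q_matvec(self, z, Q_eta, Q_phi):
        out = np.empty_like(z)
        out[self.sl_beta] = z[self.sl_beta] / self.priors.beta_var
        out[self.sl_eta] = Q_eta @ z[self.sl_eta]
        out[self.sl_phi] = Q_phi @ z[self.sl_phi]
        return out

    def q_dense(self, Q_eta, Q_phi):
        Q = np.zeros((self.dim, self.dim))
        Q[self.sl_beta, self.sl_beta] = np.eye(self.k) / self.priors.beta_var
        Q[self.sl_eta, self.sl_eta] = Q_eta.toarray()
        Q[self.sl_phi, self.sl_phi] = Q_phi
        return Q

    def loglik(self, z):
        p = expit(self.Bo @ z)
        return binomial_loglik(self.Yo, self.No, p)


def _sparse_logdet(Q: sp.spmatrix) -> float:
    lu = sp.linalg.splu(Q.tocsc(), permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0)
    d = lu.U.diagonal()
    if np.any(d <= 0):  # fall back to dense for safety
        sign, val = np.linalg.slogdet(Q.toarray())
        return float(val)
    return float(np.sum(np.log(d)))


def _newton_mode(ws: _Workspace, Q_eta, Q_phi, z0, tol, maxiter):
    """Inner Newton iteration for the conditional latent mode and its Hessian.

    Returns (z_hat, cho_factor(H), log p(Y|z_hat) + log-prior quad terms).
    Step halving guards against overshoot on flat likelihoods.
    """
    z = z0.copy()
    Qd = ws.q_dense(Q_eta, Q_phi)

    def objective(zv):
        return ws.loglik(zv) - 0.5 * ws.q_quad(zv, Q_eta, Q_phi)

    f = objective(z)
    cho = None
    for _ in range(maxiter):
        eta_lin = ws.Bo @ z
        p = np.clip(expit(eta_lin), P_CLIP, 1.0 - P_CLIP)
        grad = ws.Bo.T @ (ws.Yo - ws.No * p) - ws.q_matvec(z, Q_eta, Q_phi)
        wvec = ws.No * p * (1.0 - p)
        H = Qd + (ws.Bo.T * wvec) @ ws.Bo
        try:
            cho = cho_factor(H, lower=True)
        except LinAlgError:
            H = H + 1e-8 * np.eye(ws.dim)
            cho = cho_factor(H, lower=True)
        step = cho_solve(cho, grad)
        # backtracking: accept the longest step that improves the objective
        scale = 1.0
        for _ in range(30):
            z_new = z + scale * step
            f_new = objective(z_new)
            if f_new >= f - 1e-12:
                break
            scale *= 0.5
        rel = np.max(np.abs(scale * step)) / (1.0 + np.max(np.abs(z)))
        z, f = z_new, f_new
        if rel < tol:
            break
    return z, cho, f


def _laplace_log_marginal(ws: _Workspace, x, z0):
    """Laplace-approximated log posterior of theta (up to a constant)."""
    Q_eta, Q_phi, logdet_Q = ws.prior_blocks(x)
    z_hat, cho, f = _newton_mode(
        ws, Q_eta, Q_phi, z0, ws.controls["inner_tol"], ws.controls["inner_maxiter"]
    )
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    val = f + 0.5 * logdet_Q - 0.5 * logdet_H + _log_prior_x(x, ws.priors)
    return val, z_hat, cho


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------


def fit(
    data: ArealCounts,
    cov: CovariateStack,
    partition: AreaPartition,
    grid: GridDomain,
    priors: PriorSpec = None,
    engine: str = "laplace",
    seed: int = 0,
    controls: dict = None,
) -> PosteriorFit:
    """Fit the disaggregation model and return a :class:`PosteriorFit`.

    ``priors=None`` builds the default prior specification with the
    log-kappa prior centred at log(8/m), m being the median distance between
    prediction grid points.  ``controls`` overrides any key of
    ``DEFAULT_CONTROLS`` (mesh resolution, optimizer tolerances, MCMC chain
    settings, or ``fix`` to pin hyperparameters).
    """
    ctl = dict(DEFAULT_CONTROLS)
    if controls:
        unknown = set(controls) - set(DEFAULT_CONTROLS)
        if unknown:
            raise ValueError(f"unknown control keys: {sorted(unknown)}")
        ctl.update(controls)
    if priors is None:
        m = median_pairwise_distance(grid, seed=seed)
        priors = PriorSpec().with_median_distance(m)
    ws = _Workspace(data, cov, partition, grid, priors, ctl, seed)
    logger.info(
        "fit: engine=%s k=%d G=%d nA=%d grid=%d seed=%d",
        engine, ws.k, ws.G, ws.nA, grid.n_points, seed,
    )
    logger.info("priors: %s", priors)
    if engine == "laplace":
        return _fit_laplace(ws, seed)
    if engine == "mcmc":
        return _fit_mcmc(ws, seed)
    raise ValueError(f"unknown engine {engine!r} (choose 'laplace' or 'mcmc')")


def _pack_free(x_full, fix_mask, fix_values):
    return x_full[~fix_mask]


def _unpack_free(x_free, fix_mask, fix_values):
    x = fix_values.copy()
    x[~fix_mask] = x_free
    return x


def _fix_arrays(ctl, x0):
    fix = ctl["fix"] or {}
    unknown = set(fix) - set(_THETA_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed hyperparameters: {sorted(unknown)}")
    fix_mask = np.zeros(4, dtype=bool)
    fix_values = x0.copy()
    trans = {
        "sigma2_eta": (0, np.log),
        "kappa": (1, np.log),
        "sigma2_phi": (2, lambda v: -np.log(v)),
        "rho": (3, lambda v: np.log(v / (1.0 - v))),
    }
    for name, value in fix.items():
        idx, tr = trans[name]
        fix_mask[idx] = True
        fix_values[idx] = tr(float(value))
    return fix_mask, fix_values


def _find_mode(ws: _Workspace):
    """Optimize the Laplace-approximated theta posterior; FD Hessian at the mode.

    Returns (x_hat, cov_x, z_hat, cho, val, converged, evals, fix_mask,
    fix_values).
    """
    x0 = np.array([0.0, ws.priors.kappa_lognormal_mean, 0.0, 0.0])
    fix_mask, fix_values = _fix_arrays(ws.controls, x0)
    state = {"z": np.zeros(ws.dim), "evals": 0}

    def neg(x_free):
        x = _unpack_free(x_free, fix_mask, fix_values)
        val, z_hat, _ = _laplace_log_marginal(ws, x, state["z"])
        state["z"] = z_hat  # warm start across evaluations
        state["evals"] += 1
        return -val

    x_free0 = x0[~fix_mask]
    if x_free0.size:
        res = minimize(
            neg,
            x_free0,
            method="Powell",
            options={
                "maxiter": ws.controls["outer_maxiter"],
                "ftol": ws.controls["outer_tol"],
                "xtol": 10 * ws.controls["outer_tol"],
            },
        )
        x_hat = _unpack_free(res.x, fix_mask, fix_values)
        converged = bool(res.success)
    else:
        x_hat, converged = fix_values, True
    val, z_hat, cho = _laplace_log_marginal(ws, x_hat, state["z"])
    if not converged:
        logger.warning("outer optimizer did not report convergence (evals=%d)", state["evals"])
    n_free = int((~fix_mask).sum())
    cov_x = np.zeros((4, 4))
    if n_free:
        Hx = _fd_hessian(lambda xf: -neg(xf), x_hat[~fix_mask], h=0.05)
        cov_free = _safe_inverse(-Hx)
        cov_x[np.ix_(~fix_mask, ~fix_mask)] = cov_free
    return x_hat, cov_x, z_hat, cho, val, converged, state["evals"], fix_mask, fix_values


def _fit_laplace(ws: _Workspace, seed: int) -> PosteriorFit:
    (x_hat, cov_x, z_hat, cho, val, converged, evals, fix_mask, fix_values) = _find_mode(ws)
    n_free = int((~fix_mask).sum())
    # hyperparameter integration for prediction: self-normalized importance
    # sampling of theta with an overdispersed Gaussian proposal centred at
    # the mode.  Each draw carries its own Laplace latent component; the
    # importance weights (marginal posterior over proposal density) correct
    # both for the proposal's shape and for any mass the mode misses —
    # including the boundary-collapse case where the marginal keeps real
    # mass away from a degenerate mode.  Predictions mix the components,
    # adding the between-theta spread that a plug-in fit ignores.
    mixture = None
    n_mix = int(ws.controls["theta_mix"]) * 16 if ws.controls["theta_mix"] else 0
    if n_mix > 0 and n_free:
        from scipy.special import polygamma, psi

        cov_free = cov_x[np.ix_(~fix_mask, ~fix_mask)]
        # component A: overdispersed Gaussian at the mode
        cov_a = 1.5 * (0.5 * (cov_free + cov_free.T)) + 1e-10 * np.eye(n_free)
        # component B: the prior predictive region on the working scales —
        # guarantees proposal mass over plausible theta even when the mode
        # degenerates (e.g. the GP variance collapsing to the boundary)
        shape_c, rate_c = ws.priors.car_prec_gamma
        mean_b_full = np.array(
            [0.0, ws.priors.kappa_lognormal_mean, psi(shape_c) - np.log(rate_c),
             ws.priors.rho_logit_normal[0]]
        )
        var_b_full = np.array(
            [4.0, ws.priors.kappa_lognormal_var, float(polygamma(1, shape_c)),
             ws.priors.rho_logit_normal[1]]
        )
        mean_b = mean_b_full[~fix_mask]
        cov_b = np.diag(var_b_full[~fix_mask])
        rngm = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 313]))
        mu_a = x_hat[~fix_mask]

        def log_q(xf):
            from scipy.stats import multivariate_normal

            qa = multivariate_normal.logpdf(xf, mu_a, cov_a)
            qb = multivariate_normal.logpdf(xf, mean_b, cov_b)
            mx = max(qa, qb)
            return mx + np.log(0.5 * np.exp(qa - mx) + 0.5 * np.exp(qb - mx))

        La = cholesky(cov_a, lower=True)
        Lb = cholesky(cov_b, lower=True)
        mixture = [[z_hat, cho, 0.0]]
        logw = [float(val) - log_q(mu_a)]
        for j in range(n_mix):
            if j % 2 == 0:
                xf = mu_a + La @ rngm.standard_normal(n_free)
            else:
                xf = mean_b + Lb @ rngm.standard_normal(n_free)
            x_s = x_hat.copy()
            x_s[~fix_mask] = xf
            val_s, z_s, cho_s = _laplace_log_marginal(ws, x_s, z_hat)
            mixture.append([z_s, cho_s, 0.0])
            logw.append(float(val_s) - log_q(xf))
        logw = np.array(logw)
        wts = np.exp(logw - logw.max())
        wts /= wts.sum()
        for comp, wt in zip(mixture, wts):
            comp[2] = float(wt)
        mixture = [tuple(c) for c in mixture]
    theta_mode = _x_to_theta(x_hat, beta=z_hat[ws.sl_beta])
    summary = _laplace_summary(ws, x_hat, cov_x, z_hat, cho, seed)
    diagnostics = {
        "converged": converged,
        "outer_evals": evals,
        "log_marginal": float(val),
    }
    if not converged:
        diagnostics["warning"] = "outer optimizer hit its iteration limit"
    return PosteriorFit(
        engine="laplace",
        theta_summary=summary,
        theta_mode=theta_mode,
        latent_mean=z_hat,
        latent_chol_H=cho,
        mesh=ws.mesh,
        partition=ws.partition,
        k=ws.k,
        diagnostics=diagnostics,
        mixture=mixture,
        A_area_eta=ws.A_area_eta,
        seed=seed,
    )


def _fd_hessian(f, x, h=0.05):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            fpj = f(x + ei + ej)
            fmj = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpj - fpp - fmj + fmm + 2.0 * f0 - f(x + ej) - f(x - ej)) / (
                2.0 * h**2
            )
    return H


def _safe_inverse(A, max_var=9.0):
    """Inverse of a should-be-PD matrix, regularized if finite differences misbehave.

    Eigenvalues of the inverse are capped at ``max_var``: flat directions of
    the finite-difference Hessian would otherwise imply absurd uncertainty
    on the (log/logit) transformed hyperparameter scales.
    """
    A = 0.5 * (A + A.T)
    try:
        w, V = np.linalg.eigh(A)
    except LinAlgError:
        return np.eye(A.shape[0])
    w = np.clip(w, 1.0 / max_var, None)
    return (V / w) @ V.T


def _laplace_summary(ws, x_hat, cov_x, z_hat, cho, seed):
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2024]))
    S = 4000
    try:
        L = cholesky(cov_x + 1e-12 * np.eye(4), lower=True)
        xs = x_hat + (L @ rng.standard_normal((4, S))).T
    except LinAlgError:
        xs = np.tile(x_hat, (S, 1))
    nat = np.column_stack(
        [np.exp(xs[:, 0]), np.exp(xs[:, 1]), np.exp(-xs[:, 2]), expit(xs[:, 3])]
    )
    rows = []
    Hinv_diag = _chol_inverse_diag(cho)
    sd_beta = np.sqrt(Hinv_diag[ws.sl_beta])
    for j in range(ws.k):
        m, s = z_hat[ws.sl_beta][j], sd_beta[j]
        rows.append(("beta_%d" % j, m, s, m - 1.96 * s, m + 1.96 * s))
    for j, name in enumerate(_THETA_NAMES):
        col = nat[:, j]
        rows.append(
            (name, col.mean(), col.std(ddof=1), *np.percentile(col, [2.5, 97.5]))
        )
    r = np.sqrt(8.0) / nat[:, 1]
    rows.append(("range", r.mean(), r.std(ddof=1), *np.percentile(r, [2.5, 97.5])))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "q2.5", "q97.5"])


def _chol_inverse_diag(cho):
    Lfac, lower = cho
    n = Lfac.shape[0]
    Linv = solve_triangular(Lfac, np.eye(n), lower=lower)
    return np.sum(Linv**2, axis=0) if not lower else np.sum(Linv**2, axis=0)


# ---------------------------------------------------------------------------
# MCMC engine
# ---------------------------------------------------------------------------


def _fit_mcmc(ws: _Workspace, seed: int) -> PosteriorFit:
    import arviz as az

    ctl = ws.controls
    chains, warmup, draws = ctl["chains"], ctl["warmup"], ctl["draws"]
    # a Laplace prefit supplies the independence-proposal centre/scale for
    # theta — the hyperparameter posterior is often ridged on weak data and
    # a pure random walk mixes poorly there
    (x_hat, cov_x, _, _, _, _, _, fix_mask, fix_values) = _find_mode(ws)
    free_idx = np.flatnonzero(~fix_mask)
    prop = None
    if free_idx.size:
        cov_free = cov_x[np.ix_(~fix_mask, ~fix_mask)]
        prop_cov = 2.0 * (0.5 * (cov_free + cov_free.T)) + 1e-10 * np.eye(len(free_idx))
        prop = {
            "mean": x_hat[~fix_mask],
            "chol": cholesky(prop_cov, lower=True),
            "prec": np.linalg.inv(prop_cov),
        }
    ss = np.random.SeedSequence([int(seed) % 2**31, 777])
    chain_seeds = ss.spawn(chains)
    theta_chains = np.empty((chains, draws, 4))
    z_keep = []
    accept_stats = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        th, zk, acc = _run_chain(
            ws, x_hat, fix_mask, fix_values, free_idx, warmup, draws, rng, prop
        )
        theta_chains[c] = th
        z_keep.append(zk)
        accept_stats.append(acc)
    z_draws = np.concatenate(z_keep, axis=0)

    # diagnostics on the free hyperparameters
    diagnostics = {"accept": accept_stats}
    if free_idx.size and draws >= 4:
        ds = az.convert_to_dataset(
            {_THETA_NAMES[j]: theta_chains[:, :, j] for j in free_idx}
        )
        rhat = az.rhat(ds)
        ess = az.ess(ds)
        diagnostics["rhat"] = {v: float(rhat[v].values) for v in rhat.data_vars}
        diagnostics["ess"] = {v: float(ess[v].values) for v in ess.data_vars}
        worst = max(diagnostics["rhat"].values())
        diagnostics["converged"] = worst <= ctl["rhat_warn"]
        if worst > ctl["rhat_warn"]:
            logger.warning("MCMC split-Rhat %.3f exceeds %.2f", worst, ctl["rhat_warn"])
    else:
        diagnostics["converged"] = True

    # natural-scale summaries
    flat = theta_chains.reshape(-1, 4)
    nat = np.column_stack(
        [np.exp(flat[:, 0]), np.exp(flat[:, 1]), np.exp(-flat[:, 2]), expit(flat[:, 3])]
    )
    rows = []
    for j in range(ws.k):
        col = z_draws[:, j]
        rows.append(
            ("beta_%d" % j, col.mean(), col.std(ddof=1), *np.percentile(col, [2.5, 97.5]))
        )
    for j, name in enumerate(_THETA_NAMES):
        col = nat[:, j]
        rows.append(
            (name, col.mean(), col.std(ddof=1), *np.percentile(col, [2.5, 97.5]))
        )
    r = np.sqrt(8.0) / nat[:, 1]
    rows.append(("range", r.mean(), r.std(ddof=1), *np.percentile(r, [2.5, 97.5])))
    summary = pd.DataFrame(rows, columns=["parameter", "mean", "sd", "q2.5", "q97.5"])

    x_mean = flat.mean(axis=0)
    _, z_hat, cho = _laplace_log_marginal(ws, x_mean, z_draws.mean(axis=0))
    theta_mode = _x_to_theta(x_mean, beta=z_draws[:, : ws.k].mean(axis=0))
    return PosteriorFit(
        engine="mcmc",
        theta_summary=summary,
        theta_mode=theta_mode,
        latent_mean=z_hat,
        latent_chol_H=cho,
        mesh=ws.mesh,
        partition=ws.partition,
        k=ws.k,
        diagnostics=diagnostics,
        latent_draws=z_draws,
        A_area_eta=ws.A_area_eta,
        seed=seed,
    )


def _run_chain(ws, x0, fix_mask, fix_values, free_idx, warmup, draws, rng, prop=None):
    """One chain: Metropolis on theta + Laplace independence proposals on z.

    The theta kernel alternates a random walk with independence proposals
    from the Laplace prefit Gaussian (when available), which crosses ridges
    a random walk gets stuck on.
    """
    x = x0 + 0.1 * rng.standard_normal(4)
    x[fix_mask] = fix_values[fix_mask]
    cache = _theta_cache(ws, x, np.zeros(ws.dim))
    z = cache["z_hat"] + _draw_gauss(cache, rng)
    step = 0.25 * np.ones(4)
    n_acc_x = n_acc_z = n_tot = 0
    kept_theta = np.empty((draws, 4))
    kept_z = np.empty((draws, ws.dim))

    def log_q_ind(xf):
        d = xf - prop["mean"]
        return -0.5 * float(d @ (prop["prec"] @ d))

    def joint_logpost_minus_q(cache_j, z_j):
        """log p(Y, z, theta) - log q_Laplace(z | theta), the marginalized target."""
        lp = ws.loglik(z_j)
        lp += 0.5 * cache_j["logdet_Q"] - 0.5 * ws.q_quad(z_j, cache_j["Q_eta"], cache_j["Q_phi"])
        lp += _log_prior_x(cache_j["x"], ws.priors)
        return lp - _gauss_logpdf(cache_j, z_j)

    for it in range(warmup + draws):
        n_tot += 1
        if free_idx.size:
            # joint (theta, z) move: propose theta, then z from the Laplace
            # conditional at the proposed theta — a marginalized Metropolis
            # step that sidesteps the strong theta-z coupling of a Gibbs
            # alternation
            use_ind = prop is not None and rng.uniform() < 0.5
            x_prop = x.copy()
            if use_ind:
                x_prop[free_idx] = prop["mean"] + prop["chol"] @ rng.standard_normal(
                    len(free_idx)
                )
            else:
                x_prop[free_idx] = x[free_idx] + step[free_idx] * rng.standard_normal(
                    len(free_idx)
                )
            cache_prop = _theta_cache(ws, x_prop, cache["z_hat"])
            z_prop = cache_prop["z_hat"] + _draw_gauss(cache_prop, rng)
            num = joint_logpost_minus_q(cache_prop, z_prop)
            den = joint_logpost_minus_q(cache, z)
            if use_ind:  # independence kernel needs the proposal correction
                num -= log_q_ind(x_prop[free_idx])
                den -= log_q_ind(x[free_idx])
            if np.log(rng.uniform()) < num - den:
                x, cache, z = x_prop, cache_prop, z_prop
                n_acc_x += 1
            if it < warmup and (it + 1) % 50 == 0:
                rate = n_acc_x / n_tot
                step *= np.exp(0.6 * (rate - 0.3))
        # latent refresh at the current theta: independence proposal from
        # the Laplace approximation
        z_prop = cache["z_hat"] + _draw_gauss(cache, rng)
        num = ws.loglik(z_prop) - 0.5 * ws.q_quad(z_prop, cache["Q_eta"], cache["Q_phi"])
        num -= _gauss_logpdf(cache, z_prop)
        den = ws.loglik(z) - 0.5 * ws.q_quad(z, cache["Q_eta"], cache["Q_phi"])
        den -= _gauss_logpdf(cache, z)
        if np.log(rng.uniform()) < num - den:
            z = z_prop
            n_acc_z += 1
        if it >= warmup:
            kept_theta[it - warmup] = x
            kept_z[it - warmup] = z
    acc = {"theta": n_acc_x / max(n_tot, 1), "latent": n_acc_z / max(n_tot, 1)}
    return kept_theta, kept_z, acc


def _theta_cache(ws, x, z0):
    Q_eta, Q_phi, logdet_Q = ws.prior_blocks(x)
    z_hat, cho, _ = _newton_mode(ws, Q_eta, Q_phi, z0, 1e-5, 30)
    return {
        "x": x,
        "Q_eta": Q_eta,
        "Q_phi": Q_phi,
        "logdet_Q": logdet_Q,
        "z_hat": z_hat,
        "cho": cho,
        "logdet_H": 2.0 * float(np.sum(np.log(np.diag(cho[0])))),
    }


def _theta_cond_logpost(ws, cache, z):
    """log p(z | theta) + log p(theta) in working coordinates."""
    quad = ws.q_quad(z, cache["Q_eta"], cache["Q_phi"])
    return 0.5 * cache["logdet_Q"] - 0.5 * quad + _log_prior_x(cache["x"], ws.priors)


def _draw_gauss(cache, rng):
    Lfac, lower = cache["cho"]
    zstd = rng.standard_normal(Lfac.shape[0])
    # H = L L', draw ~ N(0, H^-1) via solving L' u = zstd
    return solve_triangular(Lfac.T if lower else Lfac, zstd, lower=not lower)


def _gauss_logpdf(cache, z):
    d = z - cache["z_hat"]
    Lfac, lower = cache["cho"]
    # cho_factor leaves junk in the unused triangle; take the clean one
    L = np.tril(Lfac) if lower else np.triu(Lfac).T
    u = L.T @ d
    return 0.5 * cache["logdet_H"] - 0.5 * float(u @ u)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(25)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _design_grid(fit_obj: PosteriorFit, cov: CovariateStack, grid: GridDomain, membership):
    mesh = fit_obj.mesh
    A_pts = mesh.A_points
    if A_pts is None or A_pts.shape[0] != grid.n_points:
        A_pts = point_projector(mesh, grid.points)
    nA = fit_obj.partition.n_areas
    membership = np.asarray(membership, dtype=int)
    rows = np.flatnonzero(membership >= 0)
    M = sp.csr_matrix(
        (np.ones(len(rows)), (rows, membership[rows])), shape=(grid.n_points, nA)
    )
    return sp.hstack([sp.csr_matrix(cov.X_grid), A_pts, M]).tocsr()


def predict(
    fit_obj: PosteriorFit,
    cov: CovariateStack,
    grid: GridDomain,
    membership: np.ndarray = None,
) -> GridPrediction:
    """Posterior mean, SD and equal-tailed 95% interval of p at every grid cell.

    Intervals are formed on the logit scale and transformed, which keeps them
    inside [0, 1]; means and SDs of p itself are integrated by Gauss-Hermite
    quadrature under the latent Gaussian (Laplace engine) or computed from
    draws (MCMC engine).  Cells with missing covariates are flagged invalid
    and excluded (NaN outputs); cells outside the partition use phi = 0.
    Area-level estimates cover every area, missing-data areas included.
    """
    if membership is None:
        membership = grid.membership
    if membership is None:
        raise ValueError("grid membership is required (run assign_membership)")
    valid = np.all(np.isfinite(cov.X_grid), axis=1)
    Xg = np.where(np.isfinite(cov.X_grid), cov.X_grid, 0.0)
    cov_safe = CovariateStack(Xg, cov.X_area, cov.names, cov.transform_log)
    Bg = _design_grid(fit_obj, cov_safe, grid, membership)
    nA = fit_obj.partition.n_areas
    A_area_eta = fit_obj.A_area_eta if fit_obj.A_area_eta is not None else fit_obj.mesh.A_areas
    B_area = sp.hstack(
        [sp.csr_matrix(cov.X_area), A_area_eta, sp.identity(nA, format="csr")]
    ).tocsr()

    if fit_obj.engine == "mcmc" and fit_obj.latent_draws is not None:
        pg = expit(np.asarray((Bg @ fit_obj.latent_draws.T)))
        mean = pg.mean(axis=1)
        sd = pg.std(axis=1, ddof=1)
        lower, upper = np.percentile(pg, [2.5, 97.5], axis=1)
        pa = expit(np.asarray(B_area @ fit_obj.latent_draws.T))
        area_mean = pa.mean(axis=1)
        area_lo, area_hi = np.percentile(pa, [2.5, 97.5], axis=1)
    else:
        mean, sd, lower, upper = _gaussian_p_summary(fit_obj, Bg)
        area_mean, _, area_lo, area_hi = _gaussian_p_summary(fit_obj, B_area)

    mean = np.where(valid, mean, np.nan)
    sd = np.where(valid, sd, np.nan)
    lower = np.where(valid, lower, np.nan)
    upper = np.where(valid, upper, np.nan)
    return GridPrediction(
        mean=mean,
        sd=sd,
        lower95=lower,
        upper95=upper,
        area_estimates=area_mean,
        area_lower95=area_lo,
        area_upper95=area_hi,
        valid=valid,
    )


def _gaussian_p_summary(fit_obj: PosteriorFit, B):
    """Mean/sd/95% bounds of p = expit(b'z) under the Laplace representation.

    With a theta mixture present the logit-scale moments pool the
    components (within- plus between-component variance); intervals come
    from the moment-matched logit-scale Gaussian, transformed — so they stay
    inside [0, 1].
    """
    Bd = B.toarray() if sp.issparse(B) else np.asarray(B)
    comps = fit_obj.mixture or [(fit_obj.latent_mean, fit_obj.latent_chol_H, 1.0)]
    p_mean_acc = np.zeros(Bd.shape[0])
    p_sq_acc = np.zeros(Bd.shape[0])
    m_acc = np.zeros(Bd.shape[0])
    msq_acc = np.zeros(Bd.shape[0])
    v_acc = np.zeros(Bd.shape[0])
    for z_mean, cho, wgt in comps:
        if wgt <= 0.0:
            continue
        m = Bd @ z_mean
        V = cho_solve(cho, Bd.T)
        var = np.maximum(np.sum(Bd.T * V, axis=0), 0.0)
        s = np.sqrt(var)
        pvals = expit(m[:, None] + s[:, None] * _GH_NODES[None, :])
        p_mean_acc += wgt * (pvals @ _GH_WEIGHTS)
        p_sq_acc += wgt * ((pvals**2) @ _GH_WEIGHTS)
        m_acc += wgt * m
        msq_acc += wgt * m**2
        v_acc += wgt * var
    p_mean = p_mean_acc
    p_var = np.maximum(p_sq_acc - p_mean**2, 0.0)
    mix_var = v_acc + np.maximum(msq_acc - m_acc**2, 0.0)
    s_mix = np.sqrt(mix_var)
    lower = expit(m_acc - 1.959963984540054 * s_mix)
    upper = expit(m_acc + 1.959963984540054 * s_mix)
    return p_mean, np.sqrt(p_var), lower, upper


def credible_interval(representation, level: float = 0.95):
    """Equal-tailed credible interval from draws or a (mean, sd) Gaussian pair.

    For a Gaussian representation the interval is mean +/- z * sd; when used
    for probabilities the caller should pass logit-scale moments and
    transform the result.  A degenerate (sd = 0 or single-draw) posterior
    collapses to a point.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    alpha = 100.0 * (1.0 - level) / 2.0
    if isinstance(representation, tuple) and len(representation) == 2:
        mean, sd = (np.asarray(v, dtype=float) for v in representation)
        from scipy.stats import norm as _norm

        zq = _norm.ppf(1.0 - (1.0 - level) / 2.0)
        return mean - zq * sd, mean + zq * sd
    draws = np.asarray(representation, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draws")
    lo = np.percentile(draws, alpha, axis=0)
    hi = np.percentile(draws, 100.0 - alpha, axis=0)
    return lo, hi
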