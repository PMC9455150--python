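"""Posterior estimation of monotone B-spline transformations.

A Gibbs scheme cycles

* ``theta_d | mu, Omega, rest`` - a truncated-normal full conditional on
  the reduced spline coefficients, sampled by one exact-HMC trajectory,
* ``mu | theta, Omega`` - the flat-prior normal conditional N(Ybar, (n Omega)^{-1}),
* ``Omega | theta, mu`` - a conjugate Wishart W(n+3, (I+S)^{-1}) step under
  a W(3, I) working prior; this precision model serves only to propagate a
  plausible dependence structure through the transformation stage, the
  sparse engines operate on the transformed data afterwards.

The returned plug-in transformation is the posterior mean:
``Z_id = sum_j thetahat_jd B_j(X_id) - muhat_d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from npnchol.splines import (
    BSplineBasis,
    TransformPrior,
    build_basis,
    build_prior,
    init_coeffs,
    select_J,
)
from npnchol.tmvn import _trajectory


@dataclass
class TransformConfig:
    nu: float = 1.0
    tau: float = 1.0
    osq: float = 1.0
    J: int | None = None  # fixed basis size; None selects by AIC per column
    J_grid: Sequence[int] = tuple(range(5, 13))
    n_iter: int = 15_000
    burn_in: int = 5_000
    seed: int | None = None
    travel: float = np.pi / 2


@dataclass
class TransformPosterior:
    """Posterior summary of the transformation stage."""

    bases: list[BSplineBasis]
    priors: list[TransformPrior]
    theta_hat: list[np.ndarray]  # per-column posterior-mean coefficients (full J_d)
    mu_hat: np.ndarray
    theta_samples: list[np.ndarray]  # per-column retained reduced draws
    mu_samples: np.ndarray
    Z: np.ndarray
    X: np.ndarray = field(repr=False, default=None)

    def transform_grid(self, d: int, grid: np.ndarray) -> np.ndarray:
        """Evaluate the fitted transform f_d (centered by mu_d) on a grid."""
        B = self.bases[d].evaluate(grid)
        return B @ self.theta_hat[d] - self.mu_hat[d]


def _sample_theta(
    prior: TransformPrior,
    CtC: np.ndarray,
    Ct_resid: np.ndarray,
    omega_dd: float,
    theta_bar: np.ndarray,
    Gamma_inv: np.ndarray,
    Gamma_inv_xi: np.ndarray,
    rng: np.random.Generator,
    travel: float,
) -> np.ndarray:
    """One exact-HMC move of the reduced coefficients from their truncated
    normal full conditional."""
    P = omega_dd * CtC + Gamma_inv
    # posterior covariance/mean via Cholesky of the precision
    Lp = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, omega_dd * Ct_resid + Gamma_inv_xi)
    # whiten x = mean + R y with R R' = P^{-1}, i.e. R = Lp^{-T}
    R = np.linalg.inv(Lp).T
    Fw = prior.F_bar @ R
    gw = prior.F_bar @ mean + prior.g_bar
    y = np.linalg.solve(R, theta_bar - mean)
    v = rng.standard_normal(len(y))
    y_new = _trajectory(y, v, Fw, gw, travel)
    if np.min(Fw @ y_new + gw) > 0:
        y = y_new
    return mean + R @ y


def estimate_transforms(X: np.ndarray, config: TransformConfig | None = None) -> TransformPosterior:
    """Fit monotone spline transforms to every column of X (values in [0, 1])."""
    config = config or TransformConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an n x p matrix")
    if np.any(~np.isfinite(X)):
        raise ValueError("X must be finite")
    if np.any((X < 0) | (X > 1)):
        raise ValueError("X must be rescaled into [0, 1]")
    n, p = X.shape
    rng = np.random.default_rng(config.seed)

    bases, priors, theta_bars = [], [], []
    C_list, o_list, CtC_list = [], [], []
    Ginv_list, Ginv_xi_list = [], []
    Y = np.empty_like(X)
    for d in range(p):
        J = config.J or select_J(X[:, d], config.J_grid, config.nu, config.tau, config.osq)
        basis = build_basis(J)
        prior = build_prior(basis, config.nu, config.tau, config.osq)
        theta0 = init_coeffs(X[:, d], basis, prior)
        B = basis.evaluate(X[:, d])
        C = B @ prior.M
        o = B @ prior.b
        bases.append(basis)
        priors.append(prior)
        theta_bars.append(prior.reduce(theta0))
        C_list.append(C)
        o_list.append(o)
        CtC_list.append(C.T @ C)
        Ginv = np.linalg.inv(prior.Gamma_bar)
        Ginv_list.append(Ginv)
        Ginv_xi_list.append(Ginv @ prior.xi_bar)
        Y[:, d] = C @ theta_bars[d] + o

    mu = Y.mean(axis=0)
    Sigma0 = np.cov(Y, rowvar=False) + 1e-6 * np.eye(p)
    omega = np.linalg.inv(Sigma0)

    keep = config.n_iter - config.burn_in
    if keep <= 0:
        raise ValueError("n_iter must exceed burn_in")
    theta_draws = [np.empty((keep, len(tb))) for tb in theta_bars]
    mu_draws = np.empty((keep, p))

    eye_p = np.eye(p)
    for it in range(config.n_iter):
        for d in range(p):
            # conditional of Y_d given the rest: N(m_d, I / omega_dd)
            resid = (Y - mu) @ omega[:, d] - (Y[:, d] - mu[d]) * omega[d, d]
            m_d = mu[d] - resid / omega[d, d]
            Ct_resid = C_list[d].T @ (m_d - o_list[d])
            theta_bars[d] = _sample_theta(
                priors[d], CtC_list[d], Ct_resid, omega[d, d], theta_bars[d],
                Ginv_list[d], Ginv_xi_list[d], rng, config.travel,
            )
            Y[:, d] = C_list[d] @ theta_bars[d] + o_list[d]
        # mu | theta, Omega  ~  N(Ybar, (n Omega)^{-1})
        Sigma_mu = np.linalg.inv(n * omega)
        mu = rng.multivariate_normal(Y.mean(axis=0), Sigma_mu, method="cholesky")
        # Omega | theta, mu  ~  W(n + 3, (I + S)^{-1})
        Zc = Y - mu
        S = Zc.T @ Zc
        scale = np.linalg.inv(eye_p + S)
        scale = 0.5 * (scale + scale.T)
        omega = stats.wishart.rvs(df=n + 3, scale=scale, random_state=rng)
        if it >= config.burn_in:
            for d in range(p):
                theta_draws[d][it - config.burn_in] = theta_bars[d]
            mu_draws[it - config.burn_in] = mu

    theta_hat = [
        priors[d].complete(theta_draws[d].mean(axis=0)) for d in range(p)
    ]
    mu_hat = mu_draws.mean(axis=0)
    Z = np.column_stack(
        [bases[d].evaluate(X[:, d]) @ theta_hat[d] - mu_hat[d] for d in range(p)]
    )
    return TransformPosterior(
        bases=bases, priors=priors, theta_hat=theta_hat, mu_hat=mu_hat,
        theta_samples=theta_draws, mu_samples=mu_draws, Z=Z, X=X,
    )
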