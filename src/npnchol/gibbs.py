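"""Gibbs samplers for the Cholesky regressions under shrinkage priors.

Both samplers work column by column on the regressions
``Z_d = sum_{k>d} beta_kd Z_k + eps_d``, reconstructing a positive-definite
precision draw ``Omega = L L'`` from every retained state.

Horseshoe: beta_kd | lambda_d^2, b_kd, sigma_d^2 ~ N(0, sigma_d^2 b_kd
c^2 lambda_d^2 / (p^2 k)) with the usual inverse-gamma auxiliary
representation of the half-Cauchy scales; the 1/k factor in the variance
implements the row-wise sparsity plan.

Bernoulli-Gaussian: binary indicators upsilon_kd multiply the design
columns; beta_kd ~ N(0, g^2) regardless of inclusion, so excluded
coefficients refresh from their prior, and upsilon_kd ~ Ber(rho*_kd).
All full conditionals follow by conjugacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from npnchol.cholesky import CholeskyParam, to_precision

_SCALE_FLOOR = 1e-300


@dataclass
class ChainResult:
    """Retained MCMC output (no thinning).

    ``beta[m]`` and ``phi[m]`` deterministically reconstruct the m-th
    precision draw; ``upsilon`` is only populated by the
    Bernoulli-Gaussian sampler.
    """

    p: int
    n: int
    beta: np.ndarray  # (M, p, p)
    phi: np.ndarray  # (M, p)
    upsilon: np.ndarray | None = None  # (M, p, p) bool
    extras: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    def omega_draw(self, m: int) -> np.ndarray:
        return to_precision(CholeskyParam(p=self.p, beta=self.beta[m], phi=self.phi[m]))

    def omega_mean(self) -> np.ndarray:
        out = np.zeros((self.p, self.p))
        for m in range(self.n_samples):
            out += self.omega_draw(m)
        return out / self.n_samples


def _inv_gamma(rng: np.random.Generator, shape: float, scale) -> np.ndarray:
    # clamp both tails: gamma variates with tiny shape underflow to zero
    with np.errstate(divide="ignore", over="ignore"):
        draw = scale / rng.gamma(shape, 1.0, size=np.shape(scale) or None)
    return np.clip(draw, _SCALE_FLOOR, 1.0 / _SCALE_FLOOR)


def gibbs_horseshoe(
    Z: np.ndarray,
    c_sparsity: float = 1.0,
    A_ig: float = 0.01,
    B_ig: float = 0.01,
    n_iter: int = 15_000,
    burn: int = 5_000,
    seed: int | np.random.Generator | None = None,
    fix_scales: bool = False,
) -> ChainResult:
    """Horseshoe-prior Gibbs chain on the Cholesky regressions of Z.

    ``fix_scales=True`` freezes every local/global scale at one (a
    degenerate test mode in which the beta conditionals reduce to a plain
    conjugate Bayesian linear model).
    """
    Z = np.asarray(Z, dtype=float)
    if np.any(~np.isfinite(Z)):
        raise ValueError("Z must be finite")
    n, p = Z.shape
    if burn >= n_iter:
        raise ValueError("n_iter must exceed burn")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    GtG = [Z[:, d + 1:].T @ Z[:, d + 1:] for d in range(p)]
    Gtz = [Z[:, d + 1:].T @ Z[:, d] for d in range(p)]
    zz = np.einsum("ij,ij->j", Z, Z)
    k_idx = [np.arange(d + 2, p + 1, dtype=float) for d in range(p)]  # 1-based rows

    beta = [np.zeros(p - 1 - d) for d in range(p)]
    sigma2 = np.ones(p)
    lam2 = np.ones(p)
    a_aux = np.ones(p)
    b_loc = [np.ones(p - 1 - d) for d in range(p)]
    h_aux = [np.ones(p - 1 - d) for d in range(p)]

    keep = n_iter - burn
    out_beta = np.zeros((keep, p, p))
    out_phi = np.empty((keep, p))
    out_lam2 = np.empty((keep, p))
    c2 = c_sparsity**2

    for it in range(n_iter):
        for d in range(p):
            m = p - 1 - d
            if m > 0:
                # prior variance of beta_kd is sigma_d^2 * v_k
                v = b_loc[d] * c2 * lam2[d] / (p**2 * k_idx[d])
                if fix_scales:
                    v = np.ones(m)
                prec = GtG[d] + np.diag(1.0 / v)
                Lp = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, Gtz[d])
                eps = np.linalg.solve(Lp.T, rng.standard_normal(m))
                beta[d] = mean + np.sqrt(sigma2[d]) * eps
                rss = zz[d] - 2.0 * beta[d] @ Gtz[d] + beta[d] @ GtG[d] @ beta[d]
                quad = np.sum(beta[d] ** 2 / v)
                sigma2[d] = _inv_gamma(rng, A_ig + 0.5 * (n + m),
                                       B_ig + 0.5 * max(rss, 0.0) + 0.5 * quad)
                if not fix_scales:
                    w2 = beta[d] ** 2 * p**2 * k_idx[d] / (2.0 * sigma2[d] * c2)
                    b_loc[d] = _inv_gamma(rng, 1.0, 1.0 / h_aux[d] + w2 / lam2[d])
                    h_aux[d] = _inv_gamma(rng, 1.0, 1.0 + 1.0 / b_loc[d])
                    lam2[d] = _inv_gamma(
                        rng, 0.5 * (m + 1), 1.0 / a_aux[d] + np.sum(w2 / b_loc[d])
                    )
                    a_aux[d] = _inv_gamma(rng, 1.0, 1.0 + 1.0 / lam2[d])
            else:
                sigma2[d] = _inv_gamma(rng, A_ig + 0.5 * n, B_ig + 0.5 * zz[d])
                if not fix_scales:
                    lam2[d] = _inv_gamma(rng, 0.5, 1.0 / a_aux[d])
                    a_aux[d] = _inv_gamma(rng, 1.0, 1.0 + 1.0 / lam2[d])
        if it >= burn:
            j = it - burn
            for d in range(p - 1):
                out_beta[j, d + 1:, d] = beta[d]
            out_phi[j] = 1.0 / sigma2
            out_lam2[j] = lam2
    return ChainResult(p=p, n=n, beta=out_beta, phi=out_phi,
                       extras={"lambda_sq": out_lam2, "c_sparsity": c_sparsity})


def gibbs_bg(
    Z: np.ndarray,
    rho_star: np.ndarray | float,
    gsq: float = 10.0,
    A_ig: float = 0.01,
    B_ig: float = 0.01,
    n_iter: int = 15_000,
    burn: int = 5_000,
    seed: int | np.random.Generator | None = None,
    upsilon_init: np.ndarray | None = None,
) -> ChainResult:
    """Bernoulli-Gaussian Gibbs chain on the Cholesky regressions of Z.

    ``upsilon_init`` is the 0/1 indicator matrix seeding the chain,
    normally the (guard-collapsed) inclusion probabilities from the
    variational tuning stage.
    """
    Z = np.asarray(Z, dtype=float)
    if np.any(~np.isfinite(Z)):
        raise ValueError("Z must be finite")
    n, p = Z.shape
    if burn >= n_iter:
        raise ValueError("n_iter must exceed burn")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = np.asarray(rho_star, dtype=float)
    if rho.ndim == 0:
        rho = np.full((p, p), float(rho))
    logit_rho = np.full((p, p), -np.inf)
    pos = np.tril(np.ones((p, p), dtype=bool), k=-1)
    with np.errstate(divide="ignore"):
        logit_rho[pos] = logit(np.clip(rho[pos], 0.0, 1.0))

    GtG = [Z[:, d + 1:].T @ Z[:, d + 1:] for d in range(p)]
    Gtz = [Z[:, d + 1:].T @ Z[:, d] for d in range(p)]
    zz = np.einsum("ij,ij->j", Z, Z)
    z_cols = [Z[:, d] for d in range(p)]

    beta = [np.zeros(p - 1 - d) for d in range(p)]
    if upsilon_init is None:
        ups = [rng.random(p - 1 - d) < rho[d + 1:, d] for d in range(p)]
    else:
        ui = np.asarray(upsilon_init)
        ups = [ui[d + 1:, d].astype(bool).copy() for d in range(p)]
    sigma2 = np.ones(p)

    keep = n_iter - burn
    out_beta = np.zeros((keep, p, p))
    out_phi = np.empty((keep, p))
    out_ups = np.zeros((keep, p, p), dtype=bool)

    for it in range(n_iter):
        for d in range(p):
            m = p - 1 - d
            if m > 0:
                u = ups[d].astype(float)
                # beta | upsilon, sigma^2: active columns couple, inactive
                # coefficients decouple to their N(0, g^2) prior
                Xu = GtG[d] * np.outer(u, u)
                prec = Xu / sigma2[d] + np.eye(m) / gsq
                Lp = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, u * Gtz[d] / sigma2[d])
                beta[d] = mean + np.linalg.solve(Lp.T, rng.standard_normal(m))
                # upsilon sitewise, with beta_k marginalized out: the
                # Bernoulli conditional compares the marginal likelihoods of
                # the residual with and without column k, which mixes far
                # better than conditioning on the current beta_k
                G = Z[:, d + 1:]
                s2 = sigma2[d]
                r = z_cols[d] - G @ (u * beta[d])
                for k in range(m):
                    gk = G[:, k]
                    gk2 = GtG[d][k, k]
                    if u[k]:
                        r = r + beta[d][k] * gk
                    gkr = float(gk @ r)
                    log_odds = (logit_rho[d + 1 + k, d]
                                - 0.5 * np.log1p(gsq * gk2 / s2)
                                + gsq * gkr**2 / (2.0 * s2 * (s2 + gsq * gk2)))
                    if log_odds < -700:
                        pk = 0.0
                    elif log_odds > 700:
                        pk = 1.0
                    else:
                        pk = expit(log_odds)
                    u[k] = 1.0 if rng.random() < pk else 0.0
                    if u[k]:
                        var_k = 1.0 / (gk2 / s2 + 1.0 / gsq)
                        beta[d][k] = (gkr / s2) * var_k \
                            + np.sqrt(var_k) * rng.standard_normal()
                        r = r - beta[d][k] * gk
                    else:
                        beta[d][k] = np.sqrt(gsq) * rng.standard_normal()
                ups[d] = u.astype(bool)
                resid = (zz[d] - 2.0 * (u * beta[d]) @ Gtz[d]
                         + (u * beta[d]) @ GtG[d] @ (u * beta[d]))
                sigma2[d] = _inv_gamma(rng, A_ig + 0.5 * n,
                                       B_ig + 0.5 * max(resid, 0.0))
            else:
                sigma2[d] = _inv_gamma(rng, A_ig + 0.5 * n, B_ig + 0.5 * zz[d])
        if it >= burn:
            j = it - burn
            for d in range(p - 1):
                out_beta[j, d + 1:, d] = beta[d] * ups[d]
                out_ups[j, d + 1:, d] = ups[d]
            out_phi[j] = 1.0 / sigma2
    return ChainResult(p=p, n=n, beta=out_beta, phi=out_phi, upsilon=out_ups)


def bg_edges(chain: ChainResult) -> np.ndarray:
    """Median-probability edges from the indicator draws of a BG chain.

    The support of omega_kd in a draw is computed through the Cholesky
    support algebra: omega_kd != 0 iff some m <= min(k, d) has both factor
    entries active (the diagonal of L is always active).
    """
    if chain.upsilon is None:
        raise ValueError("chain has no indicator draws")
    p = chain.p
    eye = np.eye(p, dtype=bool)
    prob = np.zeros((p, p))
    for m in range(chain.n_samples):
        active = chain.upsilon[m] | eye
        supp = (active.astype(np.uint8) @ active.astype(np.uint8).T) > 0
        prob += supp
    prob /= chain.n_samples
    edges = prob > 0.5
    np.fill_diagonal(edges, False)
    return edges
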