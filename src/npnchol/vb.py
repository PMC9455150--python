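"""Mean-field variational Bayes for the Bernoulli-Gaussian Cholesky regressions.

Model, per column d < p (with G = Z_{k>d} the later columns):

    Z_d | beta, sigma_d^2, upsilon ~ N(G (upsilon o beta), sigma_d^2 I)
    beta_kd ~ N(0, g^2),  upsilon_kd ~ Ber(rho*_kd),  sigma_d^2 ~ IG(A, B)

and Z_p ~ N(0, sigma_p^2 I).  The variational family factorizes as
q(beta_d) q(sigma_d^2) prod_k q(upsilon_kd) with q(beta_d) = N(alpha_d,
Sigma_d), q(sigma_d^2) = IG(A + n/2, s_d), q(upsilon_kd) = Ber(w_kd).
All coordinate updates are derived from stationarity of the variational
lower bound (VLB); the monotone ascent of the VLB across sweeps is the
correctness oracle for the derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln, logit

# w is clamped to exactly 0/1 when exp(eta) would underflow eps or overflow
_ETA_LO = np.log(2.0**-52)  # ~ -36.04
_ETA_HI = np.log(np.finfo(float).max)  # ~ 709.78


@dataclass
class VBHyper:
    """Hyperparameters of the Bernoulli-Gaussian variational model."""

    gsq: float = 10.0
    A_ig: float = 0.01
    B_ig: float = 0.01
    rho_star: np.ndarray | float = 0.5  # scalar or (p, p) with entries for k > d
    tol: float = 1e-6
    tau0: float = 1000.0
    max_sweeps: int = 500

    def __post_init__(self) -> None:
        if self.gsq <= 0 or self.A_ig <= 0 or self.B_ig <= 0 or self.tol <= 0:
            raise ValueError("gsq, A_ig, B_ig and tol must be positive")
        rs = np.asarray(self.rho_star, dtype=float)
        if np.any((rs < 0) | (rs > 1)):
            raise ValueError("rho_star entries must lie in [0, 1]")

    def rho_matrix(self, p: int) -> np.ndarray:
        rs = np.asarray(self.rho_star, dtype=float)
        if rs.ndim == 0:
            return np.full((p, p), float(rs))
        if rs.shape != (p, p):
            raise ValueError(f"rho_star must be scalar or ({p}, {p})")
        return rs


@dataclass
class VBState:
    """Variational parameters; index d runs over the p-1 regressions."""

    p: int
    n: int
    alpha: list[np.ndarray]
    Sigma: list[np.ndarray]
    s: np.ndarray  # length p; s[p-1] is the scale of q(sigma_p^2)
    tau: np.ndarray  # E_q[1/sigma_d^2]
    w: np.ndarray  # (p, p), w[k, d] for k > d
    eta: np.ndarray
    vlb_trace: list[float] = field(default_factory=list)


def init_state(Z: np.ndarray, hyper: VBHyper, w_init: np.ndarray | None = None) -> VBState:
    """Initial state; by default all indicators start at one.

    Starting from the all-included model is essential: initializing w at a
    tiny prior rho* is a fixed point of the coordinate ascent (alpha stays
    at zero, so no data evidence ever enters) and the ascent would stall at
    the empty graph.
    """
    n, p = Z.shape
    if w_init is None:
        w = np.tril(np.ones((p, p)), k=-1)
    else:
        w = np.tril(np.asarray(w_init, float), k=-1)
    a = hyper.A_ig + n / 2.0
    s = np.full(p, hyper.B_ig + 1.0)
    return VBState(
        p=p, n=n,
        alpha=[np.zeros(p - 1 - d) for d in range(p - 1)],
        Sigma=[np.eye(p - 1 - d) * hyper.gsq for d in range(p - 1)],
        s=s,
        tau=np.full(p, hyper.tau0),
        w=w,
        eta=np.where(np.tril(np.ones((p, p)), k=-1) > 0, logit(np.clip(w, 1e-12, 1 - 1e-12)), 0.0),
    )


def _expected_rss(z: np.ndarray, G: np.ndarray, alpha: np.ndarray,
                  Sigma: np.ndarray, w: np.ndarray) -> float:
    """E_q || z - G (upsilon o beta) ||^2 for one regression."""
    GtG = G.T @ G
    M2 = np.outer(w, w) + np.diag(w * (1.0 - w))
    second = GtG * M2
    return float(z @ z - 2.0 * (z @ G) @ (w * alpha)
                 + np.sum(second * (np.outer(alpha, alpha) + Sigma)))


def vb_sweep(Z: np.ndarray, state: VBState, hyper: VBHyper) -> VBState:
    """One full coordinate-ascent pass over all variational factors (in place)."""
    Z = np.asarray(Z, dtype=float)
    if np.any(~np.isfinite(Z)):
        raise ValueError("Z must be finite")
    n, p = Z.shape
    rho = hyper.rho_matrix(p)
    a = hyper.A_ig + n / 2.0
    for d in range(p - 1):
        G = Z[:, d + 1:]
        z = Z[:, d]
        GtG = G.T @ G
        Gtz = G.T @ z
        rows = np.arange(d + 1, p)
        w = state.w[rows, d].copy()
        tau = state.tau[d]

        # q(beta_d) = N(alpha, Sigma)
        M2 = np.outer(w, w) + np.diag(w * (1.0 - w))
        prec = tau * (GtG * M2) + np.eye(p - 1 - d) / hyper.gsq
        Sigma = np.linalg.inv(prec)
        Sigma = 0.5 * (Sigma + Sigma.T)
        alpha = tau * (Sigma @ (w * Gtz))

        # q(sigma_d^2): IG(A + n/2, s_d), then tau_d = E[1/sigma_d^2]
        s_d = hyper.B_ig + 0.5 * _expected_rss(z, G, alpha, Sigma, w)
        tau = a / s_d

        # q(upsilon_kd) sitewise, sequentially (proper coordinate ascent)
        S2 = np.outer(alpha, alpha) + Sigma
        lo = logit(np.clip(rho[rows, d], 0.0, 1.0))  # +-inf at the endpoints is fine
        for k in range(p - 1 - d):
            cross = float(np.dot(GtG[k] * S2[k], w)) - GtG[k, k] * S2[k, k] * w[k]
            eta_k = lo[k] + tau * (
                alpha[k] * Gtz[k] - 0.5 * S2[k, k] * GtG[k, k] - cross
            )
            w[k] = _guarded_expit(eta_k)
            state.eta[rows[k], d] = eta_k

        state.alpha[d] = alpha
        state.Sigma[d] = Sigma
        state.s[d] = s_d
        state.tau[d] = tau
        state.w[rows, d] = w
    # last column: no regression, only the noise variance
    state.s[p - 1] = hyper.B_ig + 0.5 * float(Z[:, p - 1] @ Z[:, p - 1])
    state.tau[p - 1] = a / state.s[p - 1]
    return state


def _guarded_expit(eta: float) -> float:
    if eta < _ETA_LO:
        return 0.0
    if eta > _ETA_HI:
        return 1.0
    return float(expit(eta))


def _bernoulli_term(w: np.ndarray, rho: np.ndarray) -> float:
    """sum w log(rho/w) + (1-w) log((1-rho)/(1-w)) with 0 log 0 = 0."""
    out = 0.0
    for wi, ri in zip(np.ravel(w), np.ravel(rho)):
        for prob, pref in ((wi, ri), (1.0 - wi, 1.0 - ri)):
            if prob > 0.0:
                out += prob * (np.log(pref) - np.log(prob)) if pref > 0.0 else -np.inf
    return float(out)


def compute_vlb(Z: np.ndarray, state: VBState, hyper: VBHyper,
                restricted: bool = False) -> float:
    """Variational lower bound E_q[log p(Z, kappa) - log q(kappa)].

    Valid for arbitrary (consistent) states: the inverse-gamma factors are
    evaluated at their current scales with the digamma terms retained, so
    the expression reduces to the familiar collapsed form only when each
    s_d is at its conditional optimum.  With ``restricted=True`` the terms
    of the last column (Z_p, sigma_p^2) are dropped, as used in tuning.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    A, B = hyper.A_ig, hyper.B_ig
    a = A + n / 2.0
    rho = hyper.rho_matrix(p)
    total = 0.0
    for d in range(p - 1):
        G = Z[:, d + 1:]
        z = Z[:, d]
        rows = np.arange(d + 1, p)
        alpha, Sigma, w = state.alpha[d], state.Sigma[d], state.w[rows, d]
        s_d = state.s[d]
        m = p - 1 - d
        e_log_inv = digamma(a) - np.log(s_d)
        e_inv = a / s_d
        rss = _expected_rss(z, G, alpha, Sigma, w)
        total += -0.5 * n * np.log(2 * np.pi) + 0.5 * n * e_log_inv - 0.5 * e_inv * rss
        # KL of q(beta) against N(0, g^2 I)
        sign, logdet = np.linalg.slogdet(Sigma)
        total += 0.5 * logdet + 0.5 * m - 0.5 * m * np.log(hyper.gsq) \
            - (alpha @ alpha + np.trace(Sigma)) / (2.0 * hyper.gsq)
        total += _ig_cross_entropy(A, B, a, s_d)
        total += _bernoulli_term(w, rho[rows, d])
    if not restricted:
        zp = Z[:, p - 1]
        s_p = state.s[p - 1]
        e_log_inv = digamma(a) - np.log(s_p)
        e_inv = a / s_p
        total += -0.5 * n * np.log(2 * np.pi) + 0.5 * n * e_log_inv \
            - 0.5 * e_inv * float(zp @ zp)
        total += _ig_cross_entropy(A, B, a, s_p)
    return float(total)


def _ig_cross_entropy(A: float, B: float, a: float, s: float) -> float:
    """E_q[log p(sigma^2)] - E_q[log q(sigma^2)] for q = IG(a, s), p = IG(A, B)."""
    e_log = np.log(s) - digamma(a)  # E[log sigma^2]
    e_inv = a / s
    log_p = A * np.log(B) - gammaln(A) - (A + 1.0) * e_log - B * e_inv
    log_q = a * np.log(s) - gammaln(a) - (a + 1.0) * e_log - a
    return float(log_p - log_q)


def run_vb(Z: np.ndarray, hyper: VBHyper, w_init: np.ndarray | None = None) -> VBState:
    """Coordinate ascent until the VLB change drops below ``hyper.tol``.

    Raises if the VLB ever decreases by more than 1e-8 (which would signal
    a derivation or implementation bug), warns if the sweep budget is
    exhausted before convergence.
    """
    Z = np.asarray(Z, dtype=float)
    state = init_state(Z, hyper, w_init=w_init)
    prev = -np.inf
    for sweep in range(hyper.max_sweeps):
        vb_sweep(Z, state, hyper)
        vlb = compute_vlb(Z, state, hyper)
        state.vlb_trace.append(vlb)
        if np.isfinite(prev) and vlb < prev - 1e-8:
            raise RuntimeError(
                f"VLB decreased from {prev:.10g} to {vlb:.10g} at sweep {sweep}"
            )
        if np.isfinite(prev) and abs(vlb - prev) < hyper.tol:
            return state
        prev = vlb
    warnings.warn("VB did not converge within the sweep budget; returning best state")
    return state


def tune_rho(
    Z: np.ndarray,
    hyper: VBHyper | None = None,
    grid_size: int = 50,
    paired: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage selection of the Bernoulli parameters rho*_kd.

    Stage 1 fits the variational model under the fixed sparsity-plan prior
    ``rho*_k = expit(-n/2) / (p k)`` (k the 1-based row index) to obtain
    inclusion probabilities w.  Stage 2 holds w fixed and maximizes the VLB
    restricted to the p-1 regressions over the grid
    ``rho*_kd = expit(iota_j) c_j / (p k)`` with c_j equally spaced in
    [0.1, 10] and iota_j equally spaced in [-15, 5] (paired by default, or
    the full Cartesian product).

    Returns ``(rho_star, w_stage1)``; the stage-1 w (effectively 0/1 after
    the numerical guards) also seeds the Bernoulli-Gaussian Gibbs sampler.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    hyper = hyper or VBHyper()
    if grid_size < 1:
        raise ValueError("grid must be nonempty")
    k_idx = np.arange(1, p + 1, dtype=float)  # 1-based row index of L
    inv_pk = np.tril(np.tile(1.0 / (p * k_idx[:, None]), (1, p)), k=-1)

    rho1 = expit(-0.5 * n) * inv_pk
    h1 = VBHyper(gsq=hyper.gsq, A_ig=hyper.A_ig, B_ig=hyper.B_ig,
                 rho_star=rho1, tol=hyper.tol, tau0=hyper.tau0,
                 max_sweeps=hyper.max_sweeps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state1 = run_vb(Z, h1)
    w1 = state1.w.copy()

    iotas = np.linspace(-15.0, 5.0, grid_size)
    cs = np.linspace(0.1, 10.0, grid_size)
    if paired:
        pairs = list(zip(iotas, cs))
    else:
        pairs = [(i, c) for i in iotas for c in cs]
    best_rho, best_vlb = None, -np.inf
    for iota, c in pairs:
        rho = expit(iota) * c * inv_pk
        if np.any(rho > 1.0):
            rho = np.minimum(rho, 1.0)
        h = VBHyper(gsq=hyper.gsq, A_ig=hyper.A_ig, B_ig=hyper.B_ig,
                    rho_star=rho, tol=hyper.tol, tau0=hyper.tau0)
        vlb = compute_vlb(Z, state1, h, restricted=True)
        if vlb > best_vlb:
            best_rho, best_vlb = rho, vlb
    return best_rho, w1


def vb_estimate(
    state: VBState,
    n_draws: int = 500,
    seed: int | np.random.Generator | None = None,
    hyper: VBHyper | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo summary of the variational posterior.

    Draws (beta, upsilon, sigma^2) independently from q ``n_draws`` times,
    reconstructs Omega from the effective coefficients beta o upsilon per
    draw and averages; per-draw symbolic supports of Omega are averaged and
    thresholded at > 0.5 (median probability model) for the edge matrix.
    """
    from npnchol.cholesky import CholeskyParam, to_precision

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hyper = hyper or VBHyper()
    p, n = state.p, state.n
    a = hyper.A_ig + n / 2.0
    omega_sum = np.zeros((p, p))
    support_sum = np.zeros((p, p))
    chols = [np.linalg.cholesky(state.Sigma[d]) for d in range(p - 1)]
    for _ in range(n_draws):
        beta = np.zeros((p, p))
        ups = np.zeros((p, p), dtype=bool)
        for d in range(p - 1):
            rows = np.arange(d + 1, p)
            b = state.alpha[d] + chols[d] @ rng.standard_normal(p - 1 - d)
            u = rng.random(p - 1 - d) < state.w[rows, d]
            beta[rows, d] = b * u
            ups[rows, d] = u
        sigma2 = state.s / rng.gamma(a, 1.0, size=p)
        omega = to_precision(CholeskyParam(p=p, beta=beta, phi=1.0 / sigma2))
        omega_sum += omega
        active = ups | np.eye(p, dtype=bool)
        supp = (active.astype(np.uint8) @ active.astype(np.uint8).T) > 0
        support_sum += supp
    omega_hat = omega_sum / n_draws
    edge_prob = support_sum / n_draws
    edges = edge_prob > 0.5
    np.fill_diagonal(edges, False)
    edges = edges | edges.T
    return omega_hat, edges
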