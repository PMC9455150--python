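"""From posterior output to a graph.

For the horseshoe chains (which never produce exact zeros) each precision
draw is thresholded by the 0-1-loss rule: an entry counts as nonzero when
its partial correlation exceeds half the magnitude of the corresponding
partial correlation under a non-sparse Wishart reference posterior.  The
median probability model then registers an edge wherever the mean
indicator exceeds 1/2.  A constrained maximum-likelihood refit on the
selected pattern feeds the BIC used to pick the sparsity constant c.
"""

from __future__ import annotations

import warnings

import numpy as np

from npnchol.gibbs import ChainResult


def partial_corr(omega: np.ndarray) -> np.ndarray:
    """Partial correlations ``-omega_kd / sqrt(omega_kk omega_dd)``, unit diagonal."""
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("omega must have positive diagonal")
    denom = np.sqrt(np.outer(d, d))
    out = -omega / denom
    np.fill_diagonal(out, 1.0)
    return out


def wishart_reference(Z: np.ndarray, df_prior: float = 3.0) -> np.ndarray:
    """Partial correlations of the Wishart-reference posterior mean.

    Under the non-sparse working prior ``Omega ~ W_p(df_prior, I)`` and data
    Z (n x p), conjugacy gives posterior ``W_p(n + df_prior, (I + S)^{-1})``
    with ``S = Z'Z``, whose mean is ``H = (n + df_prior)(I + S)^{-1}``.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape if Z.ndim == 2 else (0, len(Z))
    S = Z.T @ Z if n else np.zeros((p, p))
    H = (n + df_prior) * np.linalg.inv(np.eye(p) + S)
    return partial_corr(H)


def threshold_01(e: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Entrywise indicator of ``|e/j| > 0.5`` (strict).

    A zero reference with a zero estimate yields 0; a zero reference with a
    nonzero estimate yields 1 (the ratio is infinite).
    """
    e = np.asarray(e, dtype=float)
    j = np.asarray(j, dtype=float)
    if e.shape != j.shape:
        raise ValueError("shapes must match")
    if np.any(~np.isfinite(e)) or np.any(~np.isfinite(j)):
        raise ValueError("inputs must be finite")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(e) / np.abs(j)
    out = ratio > 0.5
    zero_ref = j == 0
    out[zero_ref] = e[zero_ref] != 0
    return out


def median_probability_edges(indicators) -> np.ndarray:
    """Edges with posterior inclusion frequency strictly above one half."""
    arr = np.asarray(list(indicators), dtype=float)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("need at least one square indicator draw")
    mean = arr.mean(axis=0)
    edges = mean > 0.5
    np.fill_diagonal(edges, False)
    return edges | edges.T


def horseshoe_edges(chain: ChainResult, Z: np.ndarray, df_prior: float = 3.0) -> np.ndarray:
    """0-1-loss thresholding of every draw followed by median-probability selection."""
    j = wishart_reference(Z, df_prior=df_prior)
    p = chain.p
    prob = np.zeros((p, p))
    for m in range(chain.n_samples):
        e = partial_corr(chain.omega_draw(m))
        prob += threshold_01(e, j)
    prob /= chain.n_samples
    edges = prob > 0.5
    np.fill_diagonal(edges, False)
    return edges | edges.T


def constrained_mle(
    S: np.ndarray,
    edges: np.ndarray,
    n: int,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Gaussian MLE of Omega with zeros imposed off the selected edges.

    Minimizes ``-n log det Omega + tr(Omega S)`` over symmetric matrices
    whose off-diagonal support is contained in ``edges``, by a damped
    Newton method on the free entries (the log-det barrier keeps iterates
    positive definite along the backtracked steps).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    edges = np.asarray(edges, dtype=bool)
    free_mask = edges | np.eye(p, dtype=bool)
    iu = np.triu_indices(p)
    sel = free_mask[iu]
    rows, cols = iu[0][sel], iu[1][sel]
    q = len(rows)
    offd = (rows != cols).astype(float)
    mult = 1.0 + offd  # symmetric off-diagonal entries appear twice

    def embed(x: np.ndarray) -> np.ndarray:
        om = np.zeros((p, p))
        om[rows, cols] = x
        om[cols, rows] = x
        return om

    diag_S = np.maximum(np.diag(S), 1e-12)
    x = np.where(offd > 0, 0.0, n / diag_S[rows])
    omega = embed(x)

    def objective(om: np.ndarray) -> float:
        # Cholesky doubles as the positive-definiteness barrier: slogdet
        # alone would accept indefinite iterates with det > 0
        try:
            L = np.linalg.cholesky(om)
        except np.linalg.LinAlgError:
            return np.inf
        return -2.0 * n * float(np.sum(np.log(np.diag(L)))) + float(np.sum(om * S))

    f = objective(omega)
    if not np.isfinite(f):
        raise np.linalg.LinAlgError("infeasible start for constrained MLE")
    for _ in range(max_iter):
        P = np.linalg.inv(omega)
        grad = mult * (S - n * P)[rows, cols]
        if np.max(np.abs(grad)) < tol:
            break
        # Hessian of -n log det over the free entries:
        # H_ij = n tr(P M_i P M_j) with M_i the (symmetrized) basis matrices
        Prc = P[np.ix_(rows, rows)] * P[np.ix_(cols, cols)]
        Prx = P[np.ix_(rows, cols)] * P[np.ix_(cols, rows)]
        H = n * (mult[:, None] * mult[None, :]) * 0.5 * (Prc + Prx)
        H = H + 1e-10 * np.eye(q)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.max(np.abs(H))
        t = 1.0
        g_dot = float(grad @ step)
        # near the optimum the theoretical decrease drops below the float
        # resolution of f; plain (undamped) Newton steps still contract the
        # gradient quadratically, so accept any PD iterate there
        slack = 4.0 * np.finfo(float).eps * abs(f)
        for _ in range(60):
            x_new = x - t * step
            om_new = embed(x_new)
            f_new = objective(om_new)
            if np.isfinite(f_new) and (
                f_new <= f - 1e-4 * t * g_dot
                or (1e-4 * g_dot < slack and f_new <= f + slack)
            ):
                break
            t *= 0.5
        else:
            # no representable decrease left; accept if effectively converged
            P = np.linalg.inv(omega)
            if np.max(np.abs((mult * (S - n * P)[rows, cols]))) > 10 * tol:
                warnings.warn("constrained MLE line search stalled before convergence")
            break
        x, omega, f = x_new, om_new, f_new
    else:
        P = np.linalg.inv(omega)
        if np.max(np.abs((mult * (S - n * P)[rows, cols]))) > 10 * tol:
            warnings.warn("constrained MLE did not reach the gradient tolerance")
    return omega


def bic_select(
    chains: dict[float, ChainResult],
    Z: np.ndarray,
    df_prior: float = 3.0,
) -> tuple[float, np.ndarray, np.ndarray, dict[float, float]]:
    """BIC selection of the sparsity constant c for the horseshoe engine.

    For each candidate c: select edges from its chain (0-1 loss + median
    probability), refit the constrained MLE on ``S = Z'Z``, and compute
    ``BIC = 2(-n log det + tr(Omega S)) + k log n`` with k = p + #edges.
    Ties break toward the smaller c.

    Returns ``(c_star, edges, omega_hat, bic_table)`` where omega_hat is
    the posterior-mean precision of the winning chain.
    """
    if not chains:
        raise ValueError("no candidate chains")
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    S = Z.T @ Z
    table: dict[float, float] = {}
    best = None
    for c in sorted(chains):
        chain = chains[c]
        edges = horseshoe_edges(chain, Z, df_prior=df_prior)
        omega_mle = constrained_mle(S, edges, n)
        sign, logdet = np.linalg.slogdet(omega_mle)
        neg_ll = -n * logdet + float(np.sum(omega_mle * S))
        k = chain.p + int(edges[np.triu_indices(chain.p, k=1)].sum())
        bic = 2.0 * neg_ll + k * np.log(n)
        table[c] = bic
        if best is None or bic < best[0] - 1e-12:
            best = (bic, c, edges, chain.omega_mean())
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("all candidate chains degenerate")
    return best[1], best[2], best[3], table
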