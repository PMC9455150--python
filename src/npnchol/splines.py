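"""Constrained B-spline prior for monotone marginal transformations.

Each transformation f_d is expanded in a clamped B-spline basis on [0, 1],

    f_d(x) = sum_j theta_dj B_j(x),

with a normal prior ``theta_d ~ N(zeta, o^2 I)`` conditioned on two linear
identification constraints (f_d(1/2) = 0 and f_d(3/4) - f_d(1/4) = 1) and
truncated to the monotone cone of increasing coefficients.  Conditioning on
the linear constraints leaves a degenerate normal supported on an affine
subspace; the prior is therefore re-expressed in J-2 free coordinates where
it has a proper density, with the monotone cone mapped accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.interpolate import BSpline
from scipy.stats import norm


@dataclass
class BSplineBasis:
    """Clamped B-spline basis with J functions on [0, 1]."""

    J: int
    degree: int = 3
    knots: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.J < 4:
            raise ValueError("J must be >= 4")
        if self.J < self.degree + 1:
            raise ValueError("J must be at least degree + 1")
        n_interior = self.J - self.degree - 1
        interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.zeros(self.degree + 1), interior, np.ones(self.degree + 1)]
        )

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Design matrix of shape (len(x), J); rows sum to one on [0, 1]."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any((x < 0) | (x > 1)):
            raise ValueError("evaluation points must lie in [0, 1]")
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()


@dataclass
class TransformPrior:
    """Reduced truncated-normal prior on the free B-spline coefficients.

    The full coefficient vector is recovered as ``theta = M theta_bar + b``
    (affine completion enforcing the two linear constraints exactly); the
    reduced prior is ``theta_bar ~ N(xi_bar, Gamma_bar)`` truncated to
    ``F_bar theta_bar + g_bar > 0``.
    """

    basis: BSplineBasis
    nu: float
    tau: float
    osq: float
    zeta: np.ndarray
    A_lin: np.ndarray
    c_lin: np.ndarray
    F_mono: np.ndarray
    elim_idx: np.ndarray  # two coefficients eliminated by the constraints
    free_idx: np.ndarray
    M: np.ndarray  # J x (J-2) completion map
    b: np.ndarray  # length-J completion offset
    xi: np.ndarray
    xi_bar: np.ndarray
    Gamma_bar: np.ndarray
    F_bar: np.ndarray
    g_bar: np.ndarray

    def complete(self, theta_bar: np.ndarray) -> np.ndarray:
        """Map reduced coefficients to the full J-vector satisfying A theta = c."""
        theta_bar = np.asarray(theta_bar, dtype=float)
        return theta_bar @ self.M.T + self.b

    def reduce(self, theta: np.ndarray) -> np.ndarray:
        """Extract the free coordinates of a full coefficient vector."""
        return np.asarray(theta, dtype=float)[..., self.free_idx]


def build_basis(J: int, degree: int = 3) -> BSplineBasis:
    """Clamped B-spline basis with equally spaced interior knots on [0, 1]."""
    return BSplineBasis(J=J, degree=degree)


def blom_scores(J: int, nu: float, tau: float) -> np.ndarray:
    """Increasing prior centers ``zeta_j = nu + tau * PhiInv((j - 0.375)/(J + 0.25))``."""
    j = np.arange(1, J + 1)
    return nu + tau * norm.ppf((j - 0.375) / (J + 0.25))


def build_prior(
    basis: BSplineBasis, nu: float = 1.0, tau: float = 1.0, osq: float = 1.0
) -> TransformPrior:
    """Condition N(zeta, o^2 I) on the linear constraints and reduce dimension.

    The conditional mean and covariance are the projections
    ``xi = zeta + A'(AA')^{-1}(c - A zeta)`` and
    ``Gamma = o^2 (I - A'(AA')^{-1} A)``; the reduced quantities are their
    restrictions to the J-2 free coordinates, which carry a proper density.
    The pair of eliminated coefficients is chosen by column-pivoted QR of A
    so the 2x2 solve in the completion map is well conditioned (any
    invertible choice is equivalent).
    """
    if tau <= 0 or osq <= 0:
        raise ValueError("tau and osq must be positive")
    J = basis.J
    zeta = blom_scores(J, nu, tau)
    grid = basis.evaluate(np.array([0.25, 0.5, 0.75]))
    A = np.vstack([grid[1], grid[2] - grid[0]])  # f(1/2)=0, f(3/4)-f(1/4)=1
    c = np.array([0.0, 1.0])
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("degenerate linear constraints: A is rank deficient")
    F = np.diff(np.eye(J), axis=0)  # first differences, (J-1) x J

    _, _, piv = linalg.qr(A, pivoting=True)
    elim = np.sort(piv[:2])
    free = np.sort(piv[2:])
    A_e = A[:, elim]
    A_f = A[:, free]
    # theta_elim = A_e^{-1} (c - A_f theta_free)
    M = np.zeros((J, J - 2))
    M[free, np.arange(J - 2)] = 1.0
    M[elim, :] = -linalg.solve(A_e, A_f)
    b = np.zeros(J)
    b[elim] = linalg.solve(A_e, c)

    AAt_inv = linalg.inv(A @ A.T)
    xi = zeta + A.T @ AAt_inv @ (c - A @ zeta)
    Gamma = osq * (np.eye(J) - A.T @ AAt_inv @ A)
    xi_bar = xi[free]
    Gamma_bar = Gamma[np.ix_(free, free)]
    # symmetrize against roundoff; SPD because the eliminated block is invertible
    Gamma_bar = 0.5 * (Gamma_bar + Gamma_bar.T)
    F_bar = F @ M
    g_bar = F @ b
    return TransformPrior(
        basis=basis, nu=nu, tau=tau, osq=osq, zeta=zeta,
        A_lin=A, c_lin=c, F_mono=F,
        elim_idx=elim, free_idx=free, M=M, b=b,
        xi=xi, xi_bar=xi_bar, Gamma_bar=Gamma_bar, F_bar=F_bar, g_bar=g_bar,
    )


def normal_scores(x: np.ndarray) -> np.ndarray:
    """Blom empirical normal scores of a sample (ties broken by average rank)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    from scipy.stats import rankdata

    r = rankdata(x, method="average")
    return norm.ppf((r - 0.375) / (n + 0.25))


def init_coeffs(
    x: np.ndarray,
    basis: BSplineBasis,
    prior: TransformPrior,
    margin: float = 1e-3,
) -> np.ndarray:
    """Feasible starting coefficients from a constrained least-squares spline fit.

    Fits the empirical normal scores of ``x`` by the spline subject to the
    two linear identification constraints (exactly, through the completion
    map) and the monotonicity constraints with a strict margin, so the
    result lies strictly inside the truncation region.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any((x < 0) | (x > 1)):
        raise ValueError("x must be finite and lie in [0, 1]")
    y = normal_scores(x)
    B = basis.evaluate(x)
    C = B @ prior.M
    o = B @ prior.b
    resid = y - o

    def fun(tb: np.ndarray) -> float:
        r = C @ tb - resid
        return 0.5 * float(r @ r)

    def grad(tb: np.ndarray) -> np.ndarray:
        return C.T @ (C @ tb - resid)

    # the projected Blom centers are increasing, hence a good interior start
    tb0 = prior.xi_bar.copy()
    con = optimize.LinearConstraint(prior.F_bar, margin - prior.g_bar, np.inf)
    res = optimize.minimize(
        fun, tb0, jac=grad, method="trust-constr", constraints=[con],
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 500, "verbose": 0},
    )
    tb = res.x
    slack = prior.F_bar @ tb + prior.g_bar
    if np.min(slack) <= 0:
        raise RuntimeError(
            f"monotone spline initialization infeasible: min slack {np.min(slack):.3e}"
        )
    return prior.complete(tb)


def select_J(
    x: np.ndarray,
    J_grid: Sequence[int] = tuple(range(5, 13)),
    nu: float = 1.0,
    tau: float = 1.0,
    osq: float = 1.0,
) -> int:
    """Pick the basis size by AIC of the constrained monotone spline fit.

    For each candidate J the criterion is ``-2 * max Gaussian log-likelihood
    of the fit of the normal scores + 2J`` with the residual variance at its
    MLE; ties break toward the smaller J.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("x must be finite")
    J_grid = sorted(J_grid)
    if not J_grid:
        raise ValueError("J_grid must be nonempty")
    if min(J_grid) < 4:
        raise ValueError("all candidate J must be >= 4")
    n = len(x)
    y = normal_scores(x)
    best_J, best_aic = None, np.inf
    for J in J_grid:
        basis = build_basis(J)
        prior = build_prior(basis, nu=nu, tau=tau, osq=osq)
        theta = init_coeffs(x, basis, prior)
        fit = basis.evaluate(x) @ theta
        rss = float(np.sum((y - fit) ** 2))
        sigma2 = max(rss / n, 1e-300)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        aic = -2.0 * loglik + 2.0 * J
        if aic < best_aic - 1e-12:  # strict improvement; ties keep smaller J
            best_J, best_aic = J, aic
    return int(best_J)
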