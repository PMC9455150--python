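"""Cholesky-regression parametrization of a sparse precision matrix.

A multivariate Gaussian ``Z ~ N(0, Omega^{-1})`` with ``Omega = L L'``
(``L`` lower triangular, positive diagonal) is equivalent to the set of
regressions of each variable on the *later* ones,

    Z_d = sum_{k>d} beta_kd Z_k + eps_d,    eps_d ~ N(0, sigma_d^2),

with ``beta_kd = -l_kd / l_dd`` and residual precision
``phi_d = 1/sigma_d^2 = l_dd^2``.  The module maps between the regression
parameters ``(beta, phi)`` and ``Omega``, and encodes the row-wise sparsity
plan ``rho_k = c/(p k)`` that keeps the implied sparsity of ``Omega``
roughly constant across rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CholeskyParam:
    """Regression parametrization of a precision matrix.

    Attributes
    ----------
    p : int
        Dimension.
    beta : (p, p) ndarray
        ``beta[k, d]`` holds the coefficient of variable ``k`` in the
        regression of variable ``d`` on the later variables, for ``k > d``
        (strictly lower triangle); all other entries are zero.
    phi : (p,) ndarray
        Residual precisions, all strictly positive.
    """

    p: int
    beta: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.beta.shape != (self.p, self.p):
            raise ValueError(f"beta must be ({self.p}, {self.p})")
        if self.phi.shape != (self.p,):
            raise ValueError(f"phi must have length {self.p}")
        if np.any(self.phi <= 0):
            raise ValueError("all residual precisions phi must be positive")


@dataclass
class SparsityPlan:
    """Row-wise inclusion probabilities ``rho_k = c/(p k)`` for the factor L.

    ``k`` is the 1-based row index of the lower-triangular factor.  The
    1/k decay compensates for the growing number of products that can make
    an entry of ``Omega = L L'`` nonzero, so the implied edge probability
    stays stable down the rows.
    """

    p: int
    c_sparsity: float = 1.0
    rho: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be positive")
        k = np.arange(1, self.p + 1, dtype=float)
        self.rho = np.minimum(self.c_sparsity / (self.p * k), 1.0)
        if np.any(self.rho <= 0):
            raise ValueError("c_sparsity must be positive")


def factor(param: CholeskyParam) -> np.ndarray:
    """Lower-triangular factor L with ``l_dd = sqrt(phi_d)``, ``l_kd = -beta_kd l_dd``."""
    root = np.sqrt(param.phi)
    L = -np.tril(param.beta, k=-1) * root[np.newaxis, :]
    L[np.diag_indices(param.p)] = root
    return L


def to_precision(param: CholeskyParam) -> np.ndarray:
    """Reconstruct ``Omega = L L'`` from the regression parameters.

    The result is symmetric positive definite by construction whenever all
    ``phi`` are positive.
    """
    L = factor(param)
    return L @ L.T


def from_precision(omega: np.ndarray) -> CholeskyParam:
    """Invert :func:`to_precision`: extract ``(beta, phi)`` from an SPD matrix."""
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    try:
        L = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("omega is not positive definite") from exc
    p = omega.shape[0]
    diag = np.diag(L)
    beta = -np.tril(L / diag[np.newaxis, :], k=-1)
    return CholeskyParam(p=p, beta=beta, phi=diag**2)


def support_probability(rho_k: float, rho_d: float, k: int, d: int) -> float:
    """Probability that ``omega_kd`` is nonzero under independent row supports.

    With each entry in row ``k`` of L active independently with probability
    ``rho_k``, the entry ``omega_kd = sum_m l_km l_dm`` is nonzero unless all
    ``min(k, d)`` products vanish:

        P(omega_kd != 0) = 1 - (1 - rho_k rho_d)^min(k, d).

    Indices are 1-based row indices of L.
    """
    if not (0.0 <= rho_k <= 1.0 and 0.0 <= rho_d <= 1.0):
        raise ValueError("rho values must lie in [0, 1]")
    if k < 1 or d < 1:
        raise ValueError("indices are 1-based and must be >= 1")
    return 1.0 - (1.0 - rho_k * rho_d) ** min(k, d)
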