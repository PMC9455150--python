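"""Synthetic benchmark data for nonparanormal structure learning.

Three precision-matrix families are provided:

``circle``
    ``omega_ii = 2``, ``omega_{i,i-1} = 1`` and a corner entry
    ``omega_{1,p} = 0.9`` closing the cycle.
``ar2``
    ``omega_ii = 1``, first off-diagonal 0.5, second off-diagonal 0.25.
``percent``
    A random lower-triangular factor with N(1, 0.1^2) diagonal and N(0, 1)
    entries placed uniformly at random until ``Omega = L L'`` reaches a
    requested off-diagonal nonzero percentage.

Latent Gaussian data are drawn with means on an equally spaced grid in
[0, 2]; the observed margins are produced by pushing each latent column
through a cdf (asymmetric Laplace, extreme value, or stable) whose
parameters are fitted to that column, so the observations live in (0, 1)
and are nonparanormal with the latent graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

Kind = Literal["percent", "ar2", "circle"]

#: warp families cycled over columns (d mod 3) by default
WARP_FAMILIES = ("asymmetric_laplace", "extreme_value", "stable")


@dataclass
class PrecisionSpec:
    kind: Kind
    p: int
    percent_nonzero: float | None = None
    seed: int | None = None


@dataclass
class Warp:
    """A strictly increasing map y -> G(y) in (0, 1) given by a fitted cdf."""

    family: str
    params: tuple

    def _dist(self):
        if self.family == "asymmetric_laplace":
            return stats.laplace_asymmetric(*self.params)
        if self.family == "extreme_value":
            return stats.gumbel_l(*self.params)
        if self.family == "stable":
            frozen = stats.levy_stable(*self.params)
            # default rounding near zeta flattens the cdf over ~0.5% of the
            # scale, which breaks strict monotonicity and inversion
            frozen.dist.piecewise_x_tol_near_zeta = 1e-10
            return frozen
        if self.family == "identity":
            return None
        raise ValueError(f"unknown warp family {self.family!r}")

    def __call__(self, y: np.ndarray) -> np.ndarray:
        if self.family == "identity":
            return np.asarray(y, dtype=float)
        return self._dist().cdf(y)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        if self.family == "identity":
            return np.asarray(x, dtype=float)
        dist = self._dist()
        y = np.atleast_1d(dist.ppf(np.atleast_1d(x)))
        if self.family == "stable":
            # levy_stable.ppf is only loosely accurate; polish by bisection
            from scipy.optimize import brentq

            xa = np.atleast_1d(x)
            for i in range(len(y)):
                lo, hi = y[i] - 0.5, y[i] + 0.5
                flo, fhi = dist.cdf(lo) - xa[i], dist.cdf(hi) - xa[i]
                if flo < 0 < fhi:
                    y[i] = brentq(lambda t: dist.cdf(t) - xa[i], lo, hi, xtol=1e-12)
        return y if np.ndim(x) else float(y[0])


def gen_precision(spec: PrecisionSpec) -> np.ndarray:
    """Generate an SPD precision matrix of the requested family."""
    p = spec.p
    if p < 3:
        raise ValueError("p must be >= 3")
    if spec.kind == "circle":
        omega = 2.0 * np.eye(p)
        idx = np.arange(p - 1)
        omega[idx, idx + 1] = omega[idx + 1, idx] = 1.0
        omega[0, p - 1] = omega[p - 1, 0] = 0.9
        return omega
    if spec.kind == "ar2":
        omega = np.eye(p)
        idx = np.arange(p - 1)
        omega[idx, idx + 1] = omega[idx + 1, idx] = 0.5
        idx = np.arange(p - 2)
        omega[idx, idx + 2] = omega[idx + 2, idx] = 0.25
        return omega
    if spec.kind == "percent":
        if spec.percent_nonzero is None:
            raise ValueError("percent family requires percent_nonzero")
        return _gen_percent(p, spec.percent_nonzero, np.random.default_rng(spec.seed))
    raise ValueError(f"unknown precision family {spec.kind!r}")


def _gen_percent(p: int, percent: float, rng: np.random.Generator) -> np.ndarray:
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent_nonzero must lie in [0, 100]")
    max_attempts = 50
    for _ in range(max_attempts):
        # add entries to L one at a time until Omega = LL' hits the target
        L = np.zeros((p, p))
        L[np.diag_indices(p)] = rng.normal(1.0, 0.1, size=p)
        if np.any(np.diag(L) <= 0):
            continue
        lower = [(i, j) for i in range(1, p) for j in range(i)]
        rng.shuffle(lower)
        active = np.eye(p, dtype=bool)
        target = percent / 100.0 * p * (p - 1)
        for (i, j) in lower:
            support = (active.astype(int) @ active.astype(int).T) > 0
            nonzero = support.sum() - p
            if nonzero >= target:
                break
            L[i, j] = rng.normal(0.0, 1.0)
            active[i, j] = True
        omega = L @ L.T
        try:
            np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            continue
        return omega
    raise ValueError(f"could not achieve {percent}% off-diagonal sparsity at p={p}")


def sparsity_fraction(omega: np.ndarray, atol: float = 0.0) -> float:
    """Percentage of nonzero off-diagonal entries, ``100 * #nz / (p (p-1))``."""
    omega = np.asarray(omega)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    p = omega.shape[0]
    off = ~np.eye(p, dtype=bool)
    nz = np.sum(np.abs(omega[off]) > atol)
    return 100.0 * nz / (p * (p - 1))


def true_edges(omega: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Boolean edge matrix from the off-diagonal support of a precision matrix."""
    omega = np.asarray(omega)
    edges = np.abs(omega) > atol
    np.fill_diagonal(edges, False)
    return edges


def _fit_warp(y: np.ndarray, family: str) -> Warp:
    if family == "identity":
        return Warp("identity", ())
    if family == "asymmetric_laplace":
        params = stats.laplace_asymmetric.fit(y)
        return Warp(family, tuple(params))
    if family == "extreme_value":
        params = stats.gumbel_l.fit(y)
        return Warp(family, tuple(params))
    if family == "stable":
        # quantile (McCulloch) estimates; full stable MLE is prohibitively
        # slow and numerically fragile, so it serves as a fallback target only
        try:
            alpha, beta, loc, scale = stats.levy_stable._fitstart(y)
            # keep away from the boundaries where the numerical cdf degrades
            alpha = float(np.clip(alpha, 0.5, 2.0))
            beta = float(np.clip(beta, -0.99, 0.99))
            if not np.isfinite([alpha, beta, loc, scale]).all() or scale <= 0:
                raise ValueError("non-finite quantile estimates")
        except Exception:  # moment-based fallback
            warnings.warn("stable quantile fit failed; falling back to Gaussian moments")
            alpha, beta, loc, scale = 2.0, 0.0, float(np.mean(y)), float(np.std(y) / np.sqrt(2))
        return Warp(family, (alpha, beta, loc, scale))
    raise ValueError(f"unknown warp family {family!r}")


def gen_dataset(
    omega: np.ndarray,
    n: int,
    seed: int | np.random.Generator | None = None,
    families: Sequence[str] | str = "cycle",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[Warp]]:
    """Draw latent Gaussians and warp them into observed margins.

    Parameters
    ----------
    omega : SPD precision matrix of the latent Gaussian.
    n : number of samples.
    seed : int seed or Generator.
    families : per-column warp families, or "cycle" (default: the three cdf
        families cycled over columns) or "identity" (X = Y, for engine-only
        tests that bypass the spline stage).

    Returns
    -------
    (Y, X, truth, warps) : latent data, observed data in (0, 1) (or Y itself
    under identity warps), true edge matrix, fitted warps.
    """
    omega = np.asarray(omega, dtype=float)
    p = omega.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.linspace(0.0, 2.0, p)
    cov = np.linalg.inv(omega)
    Y = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    if isinstance(families, str):
        if families == "cycle":
            fams = [WARP_FAMILIES[d % 3] for d in range(p)]
        elif families == "identity":
            fams = ["identity"] * p
        else:
            fams = [families] * p
    else:
        if len(families) != p:
            raise ValueError("families must have one entry per column")
        fams = list(families)
    warps = [_fit_warp(Y[:, d], fams[d]) for d in range(p)]
    X = np.column_stack([warps[d](Y[:, d]) for d in range(p)])
    if not all(f == "identity" for f in fams):
        eps = 1e-12
        X = np.clip(X, eps, 1.0 - eps)
    return Y, X, true_edges(omega), warps
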