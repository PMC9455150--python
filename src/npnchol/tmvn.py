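"""Exact Hamiltonian Monte Carlo for linearly truncated multivariate normals.

Samples from ``N(mean, cov)`` restricted to the polyhedron
``{x : F x + g > 0}``.  After whitening, the Hamiltonian dynamics of a
standard Gaussian are harmonic, ``x(t) = x0 cos t + v0 sin t``, so
trajectories can be followed exactly; a constraint wall is hit when
``f.x(t) + g = 0`` (a trigonometric equation solved in closed form) and the
velocity is reflected off the wall.  Each iteration integrates for a fixed
travel time (pi/2 by default), which decorrelates position from the fresh
Gaussian momentum.
"""

from __future__ import annotations

import numpy as np

_EPS_TIME = 1e-10
_MAX_REFLECTIONS = 10_000


def _hit_time(fx: float, fv: float, gj: float) -> float:
    """Earliest t > 0 with ``fx cos t + fv sin t + gj = 0``, or inf."""
    u = np.hypot(fx, fv)
    if u < abs(gj):
        return np.inf
    phi = np.arctan2(fv, fx)  # f.x(t) = u cos(t - phi)
    acos = np.arccos(np.clip(-gj / u, -1.0, 1.0))
    candidates = []
    for t in (phi + acos, phi - acos):
        t = t % (2 * np.pi)
        if t < _EPS_TIME:
            t += 2 * np.pi
        candidates.append(t)
    return min(candidates)


def _trajectory(
    x: np.ndarray, v: np.ndarray, F: np.ndarray, g: np.ndarray, travel: float
) -> np.ndarray:
    """Follow the exact dynamics from (x, v) for `travel` time with reflections."""
    t_left = travel
    norms2 = np.einsum("ij,ij->i", F, F)
    for _ in range(_MAX_REFLECTIONS):
        fx = F @ x
        fv = F @ v
        with np.errstate(invalid="ignore"):
            times = np.array(
                [_hit_time(fx[j], fv[j], g[j]) for j in range(F.shape[0])]
            )
        j = int(np.argmin(times))
        t_hit = times[j]
        if t_hit >= t_left:
            ct, st = np.cos(t_left), np.sin(t_left)
            return x * ct + v * st
        ct, st = np.cos(t_hit), np.sin(t_hit)
        x, v = x * ct + v * st, -x * st + v * ct
        # reflect off wall j
        v = v - 2.0 * (F[j] @ v) / norms2[j] * F[j]
        if F[j] @ v < 0:  # numerical safeguard: ensure inward motion
            v = v - 2.0 * (F[j] @ v) / norms2[j] * F[j]
        t_left -= t_hit
    raise RuntimeError("exact HMC exceeded the reflection budget")


def sample_tmvn(
    mean: np.ndarray,
    cov: np.ndarray,
    F: np.ndarray | None,
    g: np.ndarray | None,
    n_draws: int,
    seed: int | np.random.Generator | None = None,
    initial: np.ndarray | None = None,
    travel: float = np.pi / 2,
    burn: int = 0,
) -> np.ndarray:
    """Draw from N(mean, cov) truncated to {x : F x + g > 0}.

    Parameters
    ----------
    mean, cov : the untruncated Gaussian; cov must be SPD.
    F, g : linear constraints (None for the untruncated case).
    n_draws : retained draws.
    seed : int or Generator.
    initial : strictly feasible starting point; defaults to `mean`, which
        must then be feasible itself.
    travel : integration time per draw.
    burn : discarded initial draws.

    Returns
    -------
    (n_draws, m) array of draws, every row strictly feasible.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    m = mean.shape[0]
    try:
        R = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("cov must be positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if F is None or F.size == 0:
        z = rng.standard_normal((burn + n_draws, m))
        return mean + z[burn:] @ R.T

    F = np.atleast_2d(np.asarray(F, dtype=float))
    g = np.atleast_1d(np.asarray(g, dtype=float))
    x0 = mean if initial is None else np.asarray(initial, dtype=float)
    if np.min(F @ x0 + g) <= 0:
        raise ValueError("initial point must strictly satisfy F x + g > 0")

    # whiten: x = mean + R y;  constraints (F R) y + (F mean + g) > 0
    Fw = F @ R
    gw = F @ mean + g
    y = np.linalg.solve(R, x0 - mean)
    out = np.empty((n_draws, m))
    for it in range(burn + n_draws):
        v = rng.standard_normal(m)
        y_new = _trajectory(y, v, Fw, gw, travel)
        if np.min(Fw @ y_new + gw) > 0:
            y = y_new
        # else: discard the move (roundoff pushed the state outside); keep y
        if it >= burn:
            out[it - burn] = y
    return mean + out @ R.T
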