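"""Structure-recovery and estimation-error metrics.

Edge recovery is scored over unordered variable pairs (the strict upper
triangle of the symmetric edge matrices): sensitivity, specificity and the
Matthews correlation coefficient.  Estimation error is the scaled L1 loss,
the average absolute entrywise deviation between precision matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check_edges(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if np.any(mat != mat.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return mat.astype(bool)


def confusion(est: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts of estimated vs true edges over unordered pairs."""
    est = _check_edges(est, "est")
    truth = _check_edges(truth, "truth")
    if est.shape != truth.shape:
        raise ValueError("edge matrices must have the same dimension")
    iu = np.triu_indices(est.shape[0], k=1)
    e, t = est[iu], truth[iu]
    return ConfusionCounts(
        TP=int(np.sum(e & t)),
        TN=int(np.sum(~e & ~t)),
        FP=int(np.sum(e & ~t)),
        FN=int(np.sum(~e & t)),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, MCC).

    Any zero factor in the MCC denominator yields NaN, which happens e.g.
    when an empty graph is estimated; NaN is propagated rather than raised.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    se = tp / (tp + fn) if tp + fn > 0 else float("nan")
    sp = tn / (tn + fp) if tn + fp > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
    return se, sp, float(mcc)


def scaled_l1(omega_hat: np.ndarray, omega_true: np.ndarray) -> float:
    """Average absolute entrywise deviation, ``(1/p^2) sum |Ohat - Otrue|``."""
    omega_hat = np.asarray(omega_hat, dtype=float)
    omega_true = np.asarray(omega_true, dtype=float)
    if omega_hat.shape != omega_true.shape:
        raise ValueError("matrices must have the same shape")
    return float(np.abs(omega_hat - omega_true).mean())
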