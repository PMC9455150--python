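"""Sparse precision estimation with the variational engine.

Tunes the Bernoulli-Gaussian inclusion parameters rho*_kd on the expit
grid, runs coordinate-ascent VB on the Cholesky regressions, and reads off
the graph by the median probability model over 500 draws from the
variational posterior.
"""

import numpy as np

from npnchol.metrics import confusion, metrics
from npnchol.simulate import PrecisionSpec, gen_dataset, gen_precision
from npnchol.vb import VBHyper, run_vb, tune_rho, vb_estimate

omega = gen_precision(PrecisionSpec("circle", 25))
Y, _, truth, _ = gen_dataset(omega, 200, seed=5, families="identity")
Z = Y - Y.mean(axis=0)

rho, w_stage1 = tune_rho(Z)
state = run_vb(Z, VBHyper(rho_star=rho), w_init=w_stage1)
omega_hat, edges = vb_estimate(state, n_draws=500, seed=6)

se, sp, mcc = metrics(confusion(edges, truth))
print(f"VLB converged after {len(state.vlb_trace)} sweeps "
      f"(final value {state.vlb_trace[-1]:.2f})")
print(f"estimated {edges[np.triu_indices(25, 1)].sum()} edges, "
      f"true {truth[np.triu_indices(25, 1)].sum()}")
print(f"sensitivity {se:.3f}  specificity {sp:.3f}  MCC {mcc:.3f}")
print("MCC near 1 means the conditional-independence graph of the circle")
print("model is recovered almost exactly at n = 200.")
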