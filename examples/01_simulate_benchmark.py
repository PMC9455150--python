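"""Generate a nonparanormal benchmark dataset.

Builds the circle-model precision matrix, draws latent Gaussian data with
means on the [0, 2] grid, and warps each margin through a fitted cdf
(asymmetric Laplace / extreme value / stable, cycled over columns) so the
observations land in (0, 1) while keeping the latent graph.
"""

import numpy as np

from npnchol.simulate import PrecisionSpec, gen_dataset, gen_precision, sparsity_fraction

omega = gen_precision(PrecisionSpec(kind="circle", p=10))
print(f"circle precision, p=10: off-diagonal sparsity {sparsity_fraction(omega):.2f}%")

Y, X, truth, warps = gen_dataset(omega, n=150, seed=1, families="cycle")
print(f"latent Y: shape {Y.shape}, column std {Y.std(axis=0)[:3].round(2)} ...")
print(f"observed X in ({X.min():.3f}, {X.max():.3f}) after the cdf warps")
print("warp families:", [w.family for w in warps[:4]], "...")
print(f"true graph: {truth[np.triu_indices(10, 1)].sum()} edges "
      "(the band plus the corner entry closing the cycle)")
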