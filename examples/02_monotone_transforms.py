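"""Estimate the monotone marginal transformations.

Fits the constrained B-spline prior to warped data by exact-HMC-within-
Gibbs and checks that the plug-in transformed data recovers the latent
Gaussian up to the identification constraints (f(1/2) = 0 and
f(3/4) - f(1/4) = 1 pin location and scale, so agreement is measured by
correlation).
"""

import numpy as np

from npnchol.simulate import PrecisionSpec, gen_dataset, gen_precision
from npnchol.transform import TransformConfig, estimate_transforms

omega = gen_precision(PrecisionSpec("circle", 4))
Y, X, truth, _ = gen_dataset(omega, 200, seed=3, families="cycle")

config = TransformConfig(J=8, n_iter=400, burn_in=150, seed=0)
post = estimate_transforms(X, config)

grid = np.linspace(0, 1, 1001)
for d in range(4):
    f = post.bases[d].evaluate(grid) @ post.theta_hat[d]
    corr = np.corrcoef(post.Z[:, d], Y[:, d])[0, 1]
    print(f"column {d}: corr(Z, latent Y) = {corr:.3f}, "
          f"f(1/2) = {f[500]:+.2e}, f(3/4)-f(1/4) = {f[750]-f[250]:.6f}, "
          f"monotone: {bool(np.all(np.diff(f) > 0))}")
print("high correlations mean the spline stage undid the unknown warps; the")
print("constraint values confirm the identification restrictions hold exactly.")
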