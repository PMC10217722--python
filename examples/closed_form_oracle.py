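"""Check the empirical divergence estimator against its closed form.

For a bivariate normal with correlation rho, the Renyi pseudodistance
between the joint density and the product of the marginals has an explicit
formula (reducing to the Gaussian mutual information -0.5 ln(1 - rho^2) at
tau = 0).  The kernel-based empirical estimator should approach it as the
sample grows.
"""

import numpy as np

from rpcca import ProjectionScores, rp_normal, rp_value

rng = np.random.default_rng(3)
print(f"{'rho':>5} {'tau':>5} {'closed form':>12} {'estimate':>10} {'error':>8}")
for rho in (0.3, 0.6, 0.9):
    for tau in (0.0, 0.1, 0.5):
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2000)
        est = rp_value(ProjectionScores(z[:, 0], z[:, 1]), tau).value
        truth = rp_normal(rho, tau)
        print(f"{rho:5.1f} {tau:5.1f} {truth:12.4f} {est:10.4f} {est - truth:8.4f}")

# Errors stay within a few hundredths at n = 2000 for moderate rho.  At
# rho = 0.9 the joint density concentrates on a ridge about as narrow as
# the joint bandwidth, and the smoothing bias grows to almost -0.1: the
# estimator systematically understates very strong dependence at this
# sample size (the ordering across rho is still preserved).
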