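"""The IER lifetime model itself: density, survival, hazard, quantiles.

Evaluates the model functions at the simulation study's parameter point
(theta = 0.4, lambda = 0.8) and checks the closed-form quantile against the
cdf.  The reliability/hazard pair at the mission time x = 0.5 are the two
exact values every later estimate is judged against.
"""

import numpy as np

import ierph

p = ierph.IERParams(theta=0.4, lam=0.8)

print(f"R(0.5) = {float(ierph.reliability(0.5, p)):.7f}   "
      "(probability a unit survives past the mission time)")
print(f"H(0.5) = {float(ierph.hazard(0.5, p)):.7f}   "
      "(instantaneous failure rate at the mission time)")

u = np.array([0.1, 0.5, 0.9])
x = ierph.quantile(u, p)
print("\nquantiles:", np.array2string(x, precision=4),
      " (10%, 50%, 90% of lifetimes fall below these)")
print("round trip F(F^-1(u)) =", np.array2string(ierph.cdf(x, p), precision=10))

draws = ierph.sample_iid(100_000, p, seed=1)
print(f"\nmean of R(X) over 1e5 draws = {ierph.reliability(draws, p).mean():.4f}"
      "  (probability-integral transform: should be 0.5)")
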