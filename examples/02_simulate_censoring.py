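"""Generating progressive hybrid Type-I censored samples.

Builds the simulation study's harshest cell — n = 40 units, m = 20 target
failures, all 20 spares removed at the first failure, threshold T = 1.5 —
and draws a few samples, showing how the stopping rule splits into Case I
(m-th failure first) and Case II (clock first, terminal removal R_T > 0).
"""

import ierph

p = ierph.IERParams(0.4, 0.8)
plan = ierph.CensoringPlan(40, 20, ierph.build_scheme("scheme1", 40, 20), T=1.5)

for seed in range(5):
    s = ierph.generate_phtics(plan, p, seed=seed)
    print(f"seed {seed}: {s.case.name:>2}  r={s.r:2d} failures observed, "
          f"terminated at C={s.C:.3f}, terminal removal R_T={s.R_T}")
    # unit accounting: every unit is either failed, removed, or removed at T
    assert s.r + sum(s.removals_applied) + s.R_T == plan.n

s = ierph.generate_phtics(plan, p, seed=0)
print("\nfirst sample's failure times:")
print("  " + ", ".join(f"{t:.3f}" for t in s.times))
print("(r + removals + R_T always re-count the", plan.n, "units on test)")
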