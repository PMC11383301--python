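"""Closed-form steady state of PAR-3 membrane binding and oligomerization.

The dimensionless product x = A_tot * K_P (total subunit density times
self-affinity) fixes the oligomerization strength alpha, the geometric
size distribution A_n = A_1 alpha^(n-1), and the mean oligomer size
s = 1/(1 - alpha).  Higher PAR-3 density means larger oligomers, and --
because large oligomers detach slowly -- a lower effective dissociation
rate k_eff: binding-avidity feedback.
"""

import numpy as np

from par3dyn import (
    default_koff_table,
    effective_dissociation_rate,
    geometric_distribution,
    mean_size,
    steady_state_alpha,
)

koff = default_koff_table(50)   # k_off(1) = 2.7/s, decaying, 0 beyond n = 3

print(f"{'x = A_tot*K_P':>14} {'alpha':>7} {'mean size':>10} {'k_eff (1/s)':>12}")
for x in [0.5, 2.0, 6.2, 10.0]:
    alpha = steady_state_alpha(x)
    s = mean_size(alpha)
    A_1 = alpha if alpha > 0 else 1.0   # any A_1 > 0; k_eff is scale-free
    dist = geometric_distribution(max(A_1, 1e-9), alpha, 50)
    k_eff = effective_dissociation_rate(dist, koff)
    print(f"{x:14.1f} {alpha:7.3f} {s:10.2f} {k_eff:12.3f}")

print()
print("x = 6.2 is the uniform embryo state (alpha 0.67); x = 10 matches the")
print("measured anterior cortex (alpha 0.73, s 3.7).  k_eff falls ~4-fold")
print("between posterior-like and anterior-like densities -- the avidity")
print("feedback that accounts for roughly half of the A:P asymmetry.")
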