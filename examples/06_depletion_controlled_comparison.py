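"""Controlled comparison: positive feedback vs a fixed recruitment bias.

Both model variants reproduce the same polarized wild-type solution after
240 s of maintenance-phase dynamics.  They are then distinguished by
scanning total PAR-3 downward (mimicking RNAi depletion): the feedback
variant loses its asymmetric state below a threshold and collapses to an
A:P ratio of 1, while the fixed-bias variant levels off near the imposed
1.78-fold recruitment bias.
"""

import numpy as np

from par3dyn import FeedbackParameters, Grid1D, calibrate, depletion_response
from par3dyn.synthetic import make_initial_profile

fb = calibrate(FeedbackParameters(K_f=14.5, K_P=62.0))
init = make_initial_profile("polarized", Grid1D(), K_P=fb.K_P,
                            amplitude=0.25, ratio=8.0)
totals = np.array([1.0, 0.6, 0.3, 0.1, 0.03, 0.01])
df = depletion_response(fb, init, totals, bias_ratio=1.78)

print(f"{'total':>6} {'variant':>11} {'mean size':>10} {'A:P asymmetry':>14}")
for _, row in df.iterrows():
    print(f"{row.total:6.2f} {row.variant:>11} {row.mean_size:10.2f} "
          f"{row.asymmetry:14.2f}")
print()
print("As mean oligomer size approaches 1, the feedback variant's asymmetry")
print("approaches 1 (complete loss of polarity) while the fixed-bias variant")
print("approaches ~1.8 -- the depletion experiment discriminates the two")
print("mechanisms.")
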