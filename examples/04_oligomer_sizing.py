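"""Oligomer stoichiometry from calibrated single-molecule intensities.

Generates 5000 feature intensities from a geometric size distribution with
alpha = 0.73 (the measured anterior value) under the n-mer Gaussian model
(mean n*mu, variance n*sigma^2, sigma/mu = 0.3), then infers the size
distribution by the three estimators and refits the geometric law.
"""

import numpy as np

from par3dyn import (
    SingleMoleculeCalibration,
    fit_geometric,
    infer_sizes_bayesian,
    infer_sizes_binning,
    infer_sizes_mle,
)
from par3dyn.synthetic import GeneratorConfig, simulate_intensity_sample

cfg = GeneratorConfig(seed=11, size_alpha=0.73, mu_sm=100.0, sigma_sm=30.0)
intensities, true_sizes = simulate_intensity_sample(cfg, 5000)
calib = SingleMoleculeCalibration(mu_sm=100.0, sigma_sm=30.0)

print(f"true alpha = 0.730, true mean size = {true_sizes.mean():.2f}")
for name, fn in [("binning", infer_sizes_binning),
                 ("bayesian", infer_sizes_bayesian),
                 ("mle", infer_sizes_mle)]:
    est = fn(intensities, calib)
    _, alpha, s = fit_geometric(est)
    print(f"{name:>9}: alpha = {alpha:.3f}, mean size = {s:.2f}")
print()
print("All three estimators agree to within a few percent, as they should")
print("when the intensity model is well calibrated; interval binning is the")
print("simplest and is the default elsewhere in the package.")
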