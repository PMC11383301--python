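"""Dwell-time inference with photobleaching correction, on synthetic tracks.

Simulates a streaming single-molecule experiment (50-ms frames) in which
molecules unbind at k_off = 3.75/s while photobleaching at k_pb = 1.04/s,
plus a duty-ratio series on a slowly-releasing oligomer-bound pool
(k_app = 0.08/s).  The analysis recovers all three rates and the 1.78-fold
anterior:posterior recruitment ratio.
"""

from par3dyn import (
    build_release_curve,
    correct_rates,
    fit_release,
    photobleach_regression,
    recruitment_ratio,
)
from par3dyn.synthetic import GeneratorConfig, simulate_duty_ratio_experiment, simulate_trajectories

# --- posterior monomers: fast unbinding under continuous illumination
cfg = GeneratorConfig(seed=42, duration=40.0)
ts = simulate_trajectories(cfg, positions=False)
fit_p = fit_release(build_release_curve(ts.lifetimes("posterior")), model="double")
fit_a = fit_release(build_release_curve(ts.lifetimes("anterior")), model="double")
rates = correct_rates(fit_p, k_pb=1.04)
print(f"monomer k_off = {rates.k_all:.2f} /s   (generator truth 3.75)")
ratio = recruitment_ratio(fit_a, fit_p, 100.0, 100.0)
print(f"recruitment ratio A:P = {ratio:.2f}   (generator truth 1.78)")

# --- anterior oligomer-bound pool: duty-ratio series separates
#     disassembly from photobleaching via k_loss = k_app + k_pb * dr
cfg2 = GeneratorConfig(seed=43, lifetime_k1=0.08, duration=120.0,
                       roi_areas={"anterior": 80.0},
                       binding_rates={"anterior": 0.5})
exp = simulate_duty_ratio_experiment(cfg2)
drs, k_loss = [], []
for dr, tsd in exp.items():
    f = fit_release(build_release_curve(tsd.lifetimes("anterior")),
                    model="single", tau_min_fit=1.0)
    drs.append(dr)
    k_loss.append(f.k1)
    print(f"  dr = {dr:4.2f}:  k_loss = {f.k1:.3f} /s")
k_app, k_pb, _ = photobleach_regression(drs, k_loss)
print(f"regression: k_app = {k_app:.3f} /s (truth 0.08), "
      f"k_pb = {k_pb:.3f} /s (truth 1.04)")
print()
print("k_app is the oligomer disassembly rate k_diss; its ~47-fold gap to")
print("monomer k_off is why FRAP recovery is limited by terminal-subunit")
print("exchange.")
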