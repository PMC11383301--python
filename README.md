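# par3dyn

Kinetic and spatial modelling of PAR-3 membrane polarity in the *C. elegans*
zygote, with the single-molecule inference tools needed to constrain the
models from particle-tracking data.

PAR-3 is the keystone scaffold of the PAR polarity network. During mitosis
it remains enriched on the anterior cortex even when all posterior
inhibitors are gone, despite continuous, rapid exchange of molecules
between cytoplasm, membrane and oligomers. This package implements a
quantitative account of how that works, built from two positive feedback
loops:

1. **Binding-avidity feedback.** Membrane-bound PAR-3 monomers assemble
   head-to-tail oligomers with self-affinity `K_P = k_ass / k_diss`. At
   steady state the oligomer-size distribution is geometric,
   `A_n = A_1 α^(n-1)` with `α = K_P A_1`, mean size `s = 1/(1-α)`, and `α`
   fixed by the single dimensionless product `x = A_tot K_P` through
   `α = (1 + 2x − √(1+4x)) / 2x`. Because the membrane-detachment rate
   `k_off(n)` collapses with oligomer size (negligible for n > 3), the
   subunit-weighted effective dissociation rate
   `k_eff = Σ n k_off(n) A_n / Σ n A_n` *decreases* with PAR-3 density:
   more PAR-3 → bigger oligomers → slower loss.
2. **Recruitment feedback.** Membrane PAR-3 promotes its own monomer
   recruitment, `k_on(A) = k_basal + k_f · min(A, A_sat)`.

A spatially distributed version of the model (1-D anterior–posterior axis,
conserved cytoplasmic pool) shows that each feedback alone cannot polarize,
but together they create a regime in which a uniform and a polarized state
coexist and a transient local depletion — the sperm cue — flips the system
into the stably polarized state (*inducible polarity*).

The package also implements the measurement side: survival-curve
("release curve") analysis of single-molecule dwell times with
photobleaching correction (`k_loss = k_app + k_pb·dr` duty-ratio
regression), recruitment-ratio estimation from extrapolated zero
crossings, size-resolved dissociation rates `k_off(n) = −ln F_n`,
displacement-distribution (D₁₀₀) mobility decomposition, and three
estimators of oligomer stoichiometry from calibrated single-fluorophore
intensities. A seeded synthetic-data module generates every input with
known ground truth, so each estimator has a generate→infer→compare test.

Intended users: quantitative cell biologists and modellers working on
membrane-bound oligomerization, PAR polarity, or single-molecule kinetics
generally.

## Worked example

Steady-state consequences of binding-avidity feedback
(`examples/01_steady_state_size_distribution.py`):

```
 x = A_tot*K_P   alpha  mean size  k_eff (1/s)
           0.5   0.268       1.37        1.700
           2.0   0.500       2.00        0.913
           6.2   0.671       3.04        0.438
          10.0   0.730       3.70        0.306
```

Reading: `x = A_tot K_P` is the density–affinity product. At anterior-like
density (x ≈ 10) the model gives oligomerization strength α = 0.73 and
mean size 3.7 subunits — the experimentally measured anterior values — and
the effective dissociation rate is ~4-fold lower than at posterior-like
density, which accounts for roughly half of the ~8-fold A:P asymmetry.

Rate inference from synthetic single-molecule tracks
(`examples/03_single_molecule_rates.py`):

```
monomer k_off = 3.59 /s   (generator truth 3.75)
recruitment ratio A:P = 1.95   (generator truth 1.78)
  dr = 0.05:  k_loss = 0.140 /s
  dr = 0.10:  k_loss = 0.195 /s
  dr = 0.20:  k_loss = 0.299 /s
  dr = 1.00:  k_loss = 1.181 /s
regression: k_app = 0.084 /s (truth 0.08), k_pb = 1.096 /s (truth 1.04)
```

The other examples cover the Gillespie oracle, oligomer sizing, the LPA
phase diagram, and the depletion-scan controlled comparison between the
feedback and fixed-bias models. A thin CLI wraps the same library calls:

```bash
par3dyn reproduce frap-halftime --out out/frap --seed 1
par3dyn phase-diagram --out out/pd
```

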