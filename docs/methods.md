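# Methods

## Well-mixed size-structured kinetics

The core model tracks membrane oligomer densities `A_n` (oligomers·μm⁻²,
n = 1..n_max) with four processes:

- monomer recruitment from the cytoplasm, flux `k_on` (μm⁻²·s⁻¹);
- whole-particle membrane detachment at size-dependent rate `k_off(n)`;
- single-monomer addition at oligomer termini, rate constant `k_ass`
  (μm²·s⁻¹), giving the flux `J_n = k_ass A_1 A_n − k_diss A_{n+1}`;
- terminal-subunit loss at `k_diss` (s⁻¹).

Only monomers bind the membrane from the cytoplasm, and only monomers add
to oligomers (direct cytoplasm→oligomer binding is excluded; experimental
flux-balance arguments bound it to a small fraction). Growth is strictly
single-step at termini — oligomer–oligomer annealing and internal
fragmentation are excluded, consistent with a head-to-tail filament.
These are Becker–Döring dynamics with size-dependent removal:

```
dA_1/dt = k_on − k_off(1) A_1 − 2 J_1 − Σ_{n≥2} J_n
dA_n/dt = J_{n−1} − J_n − k_off(n) A_n          (J at the truncation = 0)
```

Aggregation conserves subunits internally, so the balance law
`d A_tot/dt = k_on − Σ n k_off(n) A_n` holds identically; the integrator
carries an auxiliary cumulative-flux state so this is checkable to solver
tolerance at every output time.

**Closed forms.** When monomer–oligomer exchange is fast relative to
removal, the assembly fluxes vanish at steady state and the distribution
is geometric, `A_n = A_1 α^{n−1}` with `α = K_P A_1`, `K_P = k_ass/k_diss`.
Then `α` solves `α = x(1−α)²` with `x = A_tot K_P`, i.e.
`α = (1+2x−√(1+4x))/2x`, `s = 1/(1−α)`, and the steady density satisfies
`P = k_on / k_eff(P)` with `k_eff` evaluated on the geometric distribution.
`steady_state_density` solves this by bracketing in α (the total off-flux
is monotone in α); a series expansion handles x → 0. The self-consistency
`P · k_eff = k_on` is exact on the truncated distribution by construction.

**Validity of the closure.** With the default rate table the removal rates
of dimers and trimers (0.8, 0.2 s⁻¹) are **not** small relative to
`k_diss = 0.08 s⁻¹`, so the exact steady state of the truncated system
deviates from geometric (small oligomers are skimmed off before they
equilibrate). `steady_state_exact` therefore solves the full truncated
system: for fixed `A_1` the balances for n ≥ 2 are linear tridiagonal in
`A_2..A_n_max` (one banded solve), and `A_1` is found by bracketing on the
total off-flux. The spatial calibration uses this exact solver; the
closure-based tests run at parameter draws with `k_diss = 400 × k_off(1)`,
where the closure error is far below the 0.1% assertion level. Those
draws also keep `k_on` below the saturating off-flux `Σ n k_off(n)/K_P`
(beyond it the model has no steady state — density runs away; the solver
reports this rather than iterating forever).

**Default rates** (configurable; quantitative work should supply measured
values): `k_off(1) = 2.7 s⁻¹`, `k_off(2) = 0.8`, `k_off(3) = 0.2`, zero
beyond size 3; `k_diss = 0.08 s⁻¹`; truncation `n_max = 50` for dynamics
(size inference caps at 20; dynamics get headroom, and the geometric tail
mass beyond the truncation is warned about above 10⁻⁶ of `A_1`). Units
package-wide: μm, s, molecules·μm⁻²; a.u. for fluorescence. Densities in
[−10⁻⁹, 0) are clipped to zero; anything more negative is an error.

**Terminal subunits.** A size-n oligomer has `min(n, 2)` terminal subunits
(linear filament). For a geometric distribution the terminal fraction is
`1 − α²` over all species and `2(1−α)/(2−α)` restricted to oligomers
(n ≥ 2). At the measured anterior α = 0.73 these give 0.467 and 0.425
respectively; the oligomer-restricted value is what a feature-based
photobleaching experiment sees, and matches the reported ≈43%.

**FRAP.** On intermediate timescales (monomer exchange fast, whole-oligomer
turnover slow) recovery within oligomers is governed by terminal-subunit
exchange alone: half-time `ln 2 / k_diss` (8.66 s at 0.08 s⁻¹), plateau =
terminal fraction. `simulate_frap` draws oligomers from a supplied
distribution and recovers each terminal slot at `k_diss` (monomers, if
included, at `k_off(1)`); the default analyses use the oligomer
subpopulation, since including monomers mixes in their much faster
turnover and pulls the aggregate half-time below `ln 2 / k_diss`.

**Gillespie oracle.** An exact SSA over {bind, unbind(n), associate,
dissociate} on a finite patch (numba-compiled inner loop, linear propensity
scan, seeded and fully deterministic). Two Monte-Carlo design rules matter
for comparisons against the closed forms: the patch should hold at least a
few hundred subunits (mean-field corrections scale as 1/N — the tests use
`area = max(100, 500/x) μm²`), and the batch-mean standard errors are only
honest when batch widths exceed the slowest relaxation time (total
occupancy decorrelates at `1/min k_off`; tests use 5-s batches against a
1-s relaxation time).

## Spatial model and nondimensionalization

The membrane is a 1-D anterior–posterior axis (length 54 μm, no-flux ends,
default 108 cells; anterior = left half). The cytoplasm is a single
well-mixed conserved pool (fast cytoplasmic diffusion limit); membrane
monomers diffuse at `D_m = 0.1 μm²/s`, oligomers are immobile (they are
sub-diffusive/cortex-bound). Local recruitment obeys

```
k_on(A) = k_basal + k_f · min(A, A_sat)
```

or, in the fixed-bias variant, `k_basal · bias(x)` independent of `A`.
Recruitment flux is proportional to the cytoplasmic pool, so total PAR-3
is conserved; being a linear invariant of the right-hand side, any
Runge–Kutta step preserves it to round-off, and runs abort if the drift
exceeds 10⁻⁶ of the total.

**Units.** Time is scaled by `1/k_diss` and density by the **total PAR-3
pool** expressed as an equivalent membrane density. In these units the
conserved total is 1, and

```
K̂_on = k_basal / (k_diss T),   K̂_f = k_f / k_diss,   K̂_P = K_P T.
```

The pool was chosen as the density scale (rather than the uniform membrane
density) because it is the convention under which the literature values of
the two feedback strengths, `(K̂_f, K̂_P) = (14.5, 62)`, reproduce the
measured anterior oligomerization state: the uniform state then sits at
`x = 0.1 × 62 = 6.2` (α = 0.67, s = 3.0) and the polarized anterior at
`x ≈ 10` (α = 0.73, s = 3.7), exactly the measured values. With the
membrane-density scale the uniform state would sit at `x = 62` (s ≈ 8), far
from any measurement.

**Calibration.** For each `(K̂_f, K̂_P)`, `K̂_on` is set so the uniform
steady state carries 10% of total PAR-3 on the membrane, using the exact
truncated steady state (not the closure), and `Â_sat` is pinned at 80% of
that uniform membrane density (= 0.08 in pool units). Recomputing the
uniform state of the calibrated model independently returns 10% to
root-finder precision — this closes the loop the calibration promises.

**LPA classification.** The local perturbation analysis reduction pins the
cytoplasmic pool at its uniform-steady-state value and studies the local
membrane ODE at one point. Candidate steady states are the one-parameter
Becker–Döring family; since `A_tot(A_1)` becomes extremely steep near
`A_1 = 1/K̂_P`, the scan runs in `A_tot` space with warm-started inversion
(an `A_1`-space scan silently skips roots — this was observed, not
conjectured). Stability is read from the eigenvalues of the full local
Jacobian (finite differences). A cell is *inducible polarity* iff at least
two stable local states coexist, the uniform state is among them, and a
set-to-low perturbation (local density at 5% of background) relaxes to the
low state; the label is insensitive to the perturbation depth across
2–20%. Root-finding failures mark cells indeterminate rather than filling
them in.

**Readouts.** Asymmetry = anterior-half mean subunit density / posterior
half; recruitment ratio = same for the local `k_on` field; mean oligomer
size on the anterior half. Halves exclude a 1-μm margin at the midline
(2 cells on the default grid), expressed in physical units so the readout
is grid-independent (halving Δx changes the 240-s asymmetry by < 1%).

**Initial profiles.** Measured maintenance-onset profiles are not
tabulated anywhere, so the polarized template is a synthetic stand-in: a
logistic step (scale 1.25 μm ≈ 5 μm transition) from an anterior plateau
of 0.25 pool units down 8-fold posteriorly, with the local geometric
composition at each point (amplitude chosen at roughly twice the
late-maintenance anterior density, matching the observed relaxation to
~50% of the late-establishment peak; ratio matching the maintained
asymmetry). Headline readouts that depend on the attractor (limiting
asymmetries, regime labels, recruitment ratios) are insensitive to this
choice; the absolute 240-s asymmetry is not, and is reported as
model-dependent. A `composition="steady"` option builds profiles from the
exact local steady distribution instead — required when a profile is meant
to *be* a steady state, because the geometric composition at the same
total density over-fluxes small-oligomer detachment and can tip the
uniform state into the coexisting low state.

**Controlled comparison (feedback vs fixed bias).** The fixed-bias variant
must reproduce the feedback model's 240-s wild-type solution. Two
calibrations are provided: (i) default — the bias profile is Picard-iterated
pointwise until the fixed-bias run reproduces the feedback model's final
density profile (all three readouts then match within 2%, enforced); (ii)
a prescribed anterior:posterior step contrast (e.g. the measured 1.78-fold
monomer recruitment asymmetry), with a single overall-gain knob matched on
the final asymmetry — here the recruitment-ratio readout equals the imposed
contrast by construction. Depletion scans rescale the initial profile with
*re-equilibrated* local size composition, since depleted embryos develop at
the depleted density; with naive linear scaling, anterior oligomers with
`k_off = 0` beyond size 3 decay only through `k_diss` and a residual tail
inflates the low-total asymmetry within 240 s. In the monomeric limit the
fixed-bias asymmetry equals the imposed recruitment contrast; the feedback
variant loses its polarized state below a threshold total and relaxes to
asymmetry 1 (runs extend in 100-s blocks until the change is < 0.1% per
block).

**Perturbation scenarios.** `no_feedback` sets `K̂_f = 0` without
recalibrating (acute loss of recruitment feedback): from the polarized
attractor the asymmetry decays monotonically but incompletely within
240 s. `cdc42_mimic` doubles basal recruitment holding `k_f` fixed
(the calibrated control plays the reduced-basal state): the posterior
density rises strictly. In this parameterization the anterior also rises
(the saturated anterior recruitment gain increases and the pool is not
depleted enough to offset it); whether the anterior instead falls depends
on a basal-scaling convention the source analyses do not pin down, and is
left open.

## Single-molecule inference

Release curves are cumulative survival histograms `H(τ_n)` = number of
trajectories with lifetime > `τ_n = n × 50 ms`; trajectories shorter than
200 ms are excluded as cytoplasmic false positives. Lifetime is defined as
(last frame − first frame + 1) × frame interval; tracks surviving to the
movie end are right-censored and dropped from release curves with their
count reported (the censoring convention is this package's choice — the
source procedures do not state one). Fits minimize weighted residuals of
`N·F(τ)`, `F = λe^{−k₁τ} + (1−λ)e^{−k₂τ}`, on `τ ≥ τ_min` (0.2 s for
double-exponential fits, 1 s for the slow anterior single-exponential
fits), with Poisson-motivated weights and two-stage log-linear starting
values. `N = F(0)` is the extrapolated binding count; per-area, per-time
ratios of `N` give recruitment ratios, with bootstrap CIs from resampling
pooled trajectories (1000 replicates by default).

Photobleaching enters as `k_loss = k_app + k_pb · dr` (duty ratio `dr`);
ordinary least squares over ≥ 3 duty ratios yields intercept `k_app` and
slope `k_pb`. Corrected rates: `k_fast/k_slow` = sorted fitted rates minus
`k_pb·dr` (reported fast ≥ slow, which also breaks the λ ↔ 1−λ label
symmetry), and the mean-lifetime rate `k_all = (∫F)/(∫τF) − k_pb·dr`,
computed in closed form from the fitted parameters. Negative corrected
rates clip to zero with a flag.

Size-resolved dissociation uses first-frame intensity size calls and
1-second survival fractions, `k_off(n) = −ln F_n`; size classes with < 20
tracks are masked, and `F_n = 0` is reported as a lower bound.

Mobility: D₁₀₀ distributions (displacements over 100 ms, all segments of
tracks ≥ 200 ms) on fixed package-wide bins (0–1.5 μm, 50-nm steps).
References: simulated Brownian motion (`D = 0.1 μm²/s`, 50-nm localization
noise at both endpoints) and a cortex-bound sub-diffusive reference
modelled as diffusion in a harmonic corral (stationary OU process) — the
source characterizes sub-diffusion only through an empirical oligomer
reference, so the corral is a documented stand-in with matching
phenomenology. Mixture weights come from non-negative least squares with a
sum-to-one constraint; near-identical references are flagged as
unidentifiable rather than resolved arbitrarily.

## Oligomer sizing

Single-fluorophore calibration fits a Gaussian to post-bleach intensities
(mean/SD MLE, one 4σ outlier pass, a mixture-BIC bimodality warning). The
n-mer intensity model is `N(n·μ_sm, n·σ_sm²)`. Three estimators over
n = 1..20: (i) interval binning with the half-open convention
`[(n−0.5)μ, (n+0.5)μ)` (sub-threshold features discarded and counted);
(ii) an empirical-Bayes EM iteration — uniform population prior,
per-feature posteriors, prior replaced by the mean posterior, iterated to
an L1 fixed point (10⁻⁶, 500 iterations, flagged if not converged; the
population-level reading of the ambiguous source procedure is adopted);
(iii) non-negative least-squares decomposition of the binned intensity
histogram into the 20 n-mer components. Geometric fits are weighted
log-linear regressions on occupied classes; the mean size is additionally
reported directly as `Σ n p_n`, since empirical histograms need not be
geometric. The density–size relation `s = 2AK_P/(√(1+4AK_P)−1)` is fitted
for `K_P` by one-parameter nonlinear least squares (≥ 4 density levels
spanning ≥ 4-fold).

## Synthetic data

All generators take a mandatory seed and return ground truth. Binding
events are Poisson in time and uniform in the ROI; dwell times are
exponential (or a two-state mixture, covering the fast/slow posterior
monomer phenomenology) competing with an exponential photobleaching clock
at `k_pb · dr`; motion is Brownian or corral-confined, frame-sampled with
localization noise (50 nm SD). Defaults mirror the measured study
conditions: 50-ms frames, `k_pb = 1.04 s⁻¹`, monomer `k_off = 3.75 s⁻¹`,
anterior:posterior binding 1.78:1, `σ_sm/μ_sm = 0.3`, anterior α = 0.73.
What the generators do **not** emulate: detection/linking errors, camera
noise, drift, within-ROI density gradients, and anything image-level —
so passing recovery tests demonstrate estimator correctness under the
stated statistical model, not robustness to tracking artifacts.

## Problem sizes and numerics

Default test/analysis scales, chosen as representative working sizes:
5000 trajectories or intensity features per recovery run, 10⁴–10⁶ SSA
events, 108-cell PDE grids with `n_max = 50` (≈5400 coupled ODEs,
explicit RK45 — the fastest local rate, `k_off(1)/k_diss ≈ 34`, is mild),
240-s maintenance runs, and 10×10 or smaller LPA phase diagrams. The
acceptance script completes in well under a minute; the full test suite in
about one minute.

## Known limitations

- The closure-based formulas assume fast exchange; with the default rate
  table the exact and closure steady states differ by several percent, and
  the package is explicit about which solver is used where.
- Absolute 240-s asymmetries depend on the synthetic initial profile and
  should be read as model-conditional; regime structure and limiting
  behaviors do not.
- No cortical flow/advection, no PAR-1/CHIN-1 antagonism circuitry, no
  2-D membrane geometry, no filament mechanics.
- The sub-diffusive mobility reference is a modelled stand-in, not an
  empirical oligomer distribution.
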