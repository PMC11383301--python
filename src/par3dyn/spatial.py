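"""Spatially distributed PAR-3 model with positive feedback on monomer recruitment.

The well-mixed size-structured kinetics are extended along a 1-D
anterior-posterior axis (default 54 um, no-flux ends).  Monomer recruitment
depends on the local membrane PAR-3 subunit density A through

    k_on(A) = k_basal + k_f * min(A, A_sat)

(or, in the fixed-bias variant, a time-constant spatial multiplier on
basal recruitment that is independent of A).  The cytoplasm is a single
well-mixed conserved pool; membrane monomers diffuse slowly (default
0.1 um^2/s) and oligomers are immobile.

Everything here works in dimensionless units: time is scaled by 1/k_diss
and densities by the total PAR-3 pool expressed as an equivalent membrane
density, so the conserved total is 1, the uniform steady state carries
``membrane_fraction`` (default 0.10) on the membrane, and the saturation
density is ``sat_fraction * membrane_fraction`` (default 0.08).  In these
units K_on = k_basal/(k_diss*T), K_f = k_f/k_diss and K_P = K_P_physical*T.
This convention reproduces the measured anterior oligomerization strength
(alpha ~ 0.73, s ~ 3.7) at the embryo point (K_f, K_P) = (14.5, 62).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetics import (
    ConvergenceError,
    KineticsError,
    RateParameters,
    SizeDistribution,
    becker_doring_profile,
    becker_doring_rhs,
    default_koff_table,
    solve_a1_for_total,
)

__all__ = [
    "FeedbackParameters",
    "Grid1D",
    "FieldState",
    "RegimeLabel",
    "PhaseDiagram",
    "MaintenanceResult",
    "CalibrationMismatch",
    "recruitment_rate",
    "calibrate",
    "local_steady_states",
    "lpa_classify",
    "phase_diagram",
    "simulate_maintenance",
    "depletion_response",
    "perturbation_scenarios",
    "PERTURBATION_SCENARIOS",
]

DEFAULT_K_DISS = 0.08  # s^-1, measured oligomer disassembly rate


class CalibrationMismatch(RuntimeError):
    """Controlled comparison failed to match the reference readouts."""


@dataclass
class FeedbackParameters:
    """Dimensionless parameters of the recruitment-feedback model.

    K_f and K_P are the two feedback strengths (monomer recruitment and
    self-affinity / binding avidity).  K_on and A_sat are set by
    :func:`calibrate`.  ``bias_profile`` (fixed-bias mode only) is a spatial
    multiplier on basal recruitment, constant in time.
    """

    K_f: float
    K_P: float
    koff_hat: np.ndarray = None
    n_max: int = 50
    membrane_fraction: float = 0.10
    sat_fraction: float = 0.80
    K_on: float | None = None
    A_sat: float | None = None
    bias_mode: str = "positive_feedback"
    bias_profile: np.ndarray | None = None

    def __post_init__(self):
        if self.koff_hat is None:
            self.koff_hat = default_koff_table(self.n_max) / DEFAULT_K_DISS
        self.koff_hat = np.asarray(self.koff_hat, dtype=float)
        if self.K_f < 0 or self.K_P < 0:
            raise KineticsError("feedback strengths must be >= 0")
        if self.bias_mode not in ("positive_feedback", "fixed_bias"):
            raise KineticsError(f"unknown bias_mode {self.bias_mode!r}")
        if self.bias_mode == "positive_feedback" and self.bias_profile is not None:
            raise KineticsError("bias_profile only applies in fixed_bias mode")

    @property
    def rate_params(self) -> RateParameters:
        """Dimensionless kinetics: k_diss = 1, k_ass = K_P."""
        return RateParameters(k_on=0.0, k_off_by_size=self.koff_hat,
                              k_ass=self.K_P, k_diss=1.0, n_max=self.n_max)

    @classmethod
    def from_physical(cls, k_basal: float, k_f: float, K_P: float, T: float,
                      k_diss: float = DEFAULT_K_DISS,
                      k_off_by_size: np.ndarray | None = None,
                      n_max: int = 50, **kw) -> "FeedbackParameters":
        """Build from physical rates: k_basal (um^-2 s^-1 per unit cytoplasmic
        fraction), k_f (s^-1), K_P (um^2), total pool T (um^-2 equivalent)."""
        koff = default_koff_table(n_max) if k_off_by_size is None else np.asarray(k_off_by_size)
        fb = cls(K_f=k_f / k_diss, K_P=K_P * T, koff_hat=koff / k_diss,
                 n_max=n_max, **kw)
        fb.K_on = k_basal / (k_diss * T)
        return fb

    def replace(self, **kw) -> "FeedbackParameters":
        return dataclasses.replace(self, **kw)


def recruitment_rate(A, fb: FeedbackParameters, bias=None):
    """Local recruitment rate constant k_on(A) (per unit cytoplasmic pool).

    positive_feedback: K_on * (1 + K_f * min(A, A_sat)); fixed_bias:
    K_on * bias, independent of A.
    """
    if fb.K_on is None:
        raise KineticsError("parameters are not calibrated (K_on unset)")
    if fb.bias_mode == "fixed_bias":
        b = bias if bias is not None else fb.bias_profile
        if b is None:
            raise KineticsError("fixed_bias mode requires a bias_profile")
        return fb.K_on * np.asarray(b) * np.ones_like(np.asarray(A, dtype=float))
    A = np.asarray(A, dtype=float)
    out = fb.K_on * (1.0 + fb.K_f * np.minimum(A, fb.A_sat))
    return out


def _uniform_membrane_distribution(fb: FeedbackParameters,
                                   A_target: float) -> SizeDistribution:
    """Exact Becker-Doring steady distribution with total subunit density A_target."""
    params = fb.rate_params
    if fb.K_P == 0:
        A = np.zeros(fb.n_max)
        A[0] = A_target
        return SizeDistribution(A)
    a1 = solve_a1_for_total(params, A_target)
    return becker_doring_profile(a1, params)


def _off_flux(dist: SizeDistribution, koff_hat: np.ndarray) -> float:
    return float(np.dot(dist.n * dist.A, koff_hat))


def calibrate(fb: FeedbackParameters, total: float = 1.0,
              target_membrane_fraction: float | None = None,
              sat_fraction: float | None = None) -> FeedbackParameters:
    """Set K_on so the uniform steady state carries the target membrane fraction.

    A_sat is pinned at ``sat_fraction`` times the uniform steady-state
    membrane density.  The uniform membrane distribution is the exact
    steady state of the truncated size-structured system, so recomputing
    the uniform state of the calibrated model returns the target fraction
    to root-finder precision.
    """
    mf = fb.membrane_fraction if target_membrane_fraction is None else target_membrane_fraction
    sf = fb.sat_fraction if sat_fraction is None else sat_fraction
    A_uni = mf * total
    C_uni = total - A_uni
    if C_uni <= 0:
        raise ConvergenceError("infeasible: membrane fraction >= 1", fraction=mf)
    dist = _uniform_membrane_distribution(fb, A_uni)
    phi = _off_flux(dist, fb.koff_hat)
    A_sat = sf * A_uni
    gain = 1.0 + fb.K_f * min(A_uni, A_sat)
    K_on = phi / (gain * C_uni)
    out = fb.replace(K_on=K_on, A_sat=A_sat,
                     membrane_fraction=mf, sat_fraction=sf)
    # self-consistency: the uniform state of the calibrated model
    frac = uniform_membrane_fraction(out, total=total)
    if abs(frac - mf) > 1e-8:
        raise ConvergenceError("calibration loop failed to close",
                               achieved=frac, target=mf)
    return out


def uniform_membrane_fraction(fb: FeedbackParameters, total: float = 1.0) -> float:
    """Membrane-bound fraction at the spatially uniform steady state,
    recomputed from the calibrated model by root-finding on the full system."""

    def h(A_tot):
        dist = _uniform_membrane_distribution(fb, A_tot)
        g = recruitment_rate(A_tot, fb, bias=1.0) * (total - A_tot)
        return float(g) - _off_flux(dist, fb.koff_hat)

    # multiple uniform steady states can coexist (that is the point of the
    # model); report the one at the calibration target, found by growing the
    # bracket outward from it
    target = fb.membrane_fraction * total
    for eps in (0.02, 0.05, 0.1, 0.3, 0.6):
        lo, hi = (1 - eps) * target, min((1 + eps) * target, 0.999 * total)
        if h(lo) * h(hi) < 0:
            A = brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16)
            return A / total
    raise ConvergenceError("no uniform steady state near the calibration target",
                           target=fb.membrane_fraction)


# ---------------------------------------------------------------------------
# local perturbation analysis
# ---------------------------------------------------------------------------

@dataclass
class LocalState:
    A_tot: float
    A: np.ndarray
    stable: bool
    max_eig: float


@dataclass
class RegimeLabel:
    label: str                      # no_polarity | inducible_polarity | indeterminate
    states: list = field(default_factory=list)
    n_stable: int = 0
    transition_ok: bool = False
    message: str = ""


def _local_rhs(A: np.ndarray, fb: FeedbackParameters, C: float) -> np.ndarray:
    n = np.arange(1, fb.n_max + 1)
    A_tot = float(np.dot(n, A))
    g = float(recruitment_rate(A_tot, fb, bias=1.0)) * C
    return becker_doring_rhs(A, g, fb.koff_hat, fb.K_P, 1.0)


def _local_jacobian(A: np.ndarray, fb: FeedbackParameters, C: float,
                    eps: float = 1e-7) -> np.ndarray:
    nmax = len(A)
    J = np.empty((nmax, nmax))
    scale = max(np.abs(A).max(), 1e-3)
    for j in range(nmax):
        dA = np.zeros(nmax)
        dA[j] = eps * scale
        J[:, j] = (_local_rhs(A + dA, fb, C) - _local_rhs(A - dA, fb, C)) / (2 * eps * scale)
    return J


def local_steady_states(fb: FeedbackParameters, total: float = 1.0,
                        n_scan: int = 240) -> list[LocalState]:
    """Steady states of the local membrane ODE with the cytoplasmic pool
    pinned at its uniform-steady-state value (the LPA reduction).

    Candidate steady profiles are the one-parameter Becker-Doring family;
    the scan runs in total-density space (A_tot(A_1) is extremely steep near
    A_1 = 1/K_P, so an A_1-space scan would skip roots), inverting
    A_tot -> A_1 with warm-started bracketing.
    """
    if fb.K_on is None:
        raise KineticsError("calibrate() first")
    C = total * (1.0 - fb.membrane_fraction)
    params = fb.rate_params

    if fb.K_P == 0:
        a1_hi = total
    else:
        a1_hi = solve_a1_for_total(params, total)

    def a_tot_of(a1):
        return becker_doring_profile(a1, params).A_tot

    A_grid = np.geomspace(1e-7 * total, (1.0 - 1e-7) * total, n_scan)
    a1_grid = np.empty(n_scan)
    lo = 0.0
    for i, A_t in enumerate(A_grid):
        a1_grid[i] = brentq(lambda a: a_tot_of(a) - A_t, lo, a1_hi,
                            xtol=1e-300, rtol=4e-15)
        lo = a1_grid[i]

    def balance_at(a1):
        dist = becker_doring_profile(a1, params)
        g = float(recruitment_rate(dist.A_tot, fb, bias=1.0)) * C
        return g - _off_flux(dist, fb.koff_hat)

    vals = np.array([balance_at(a) for a in a1_grid])
    roots = []
    if balance_at(0.0) == 0.0:
        roots.append(0.0)
    for i in range(n_scan - 1):
        if vals[i] == 0.0:
            roots.append(a1_grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(balance_at, a1_grid[i], a1_grid[i + 1],
                                xtol=1e-300, rtol=8.9e-16))
    states = []
    for a1 in roots:
        dist = becker_doring_profile(a1, params)
        if any(abs(dist.A_tot - s.A_tot) < 1e-7 * max(1.0, s.A_tot) for s in states):
            continue
        Jm = _local_jacobian(dist.A, fb, C)
        lam = float(np.max(np.linalg.eigvals(Jm).real))
        states.append(LocalState(A_tot=dist.A_tot, A=dist.A,
                                 stable=lam < -1e-10, max_eig=lam))
    states.sort(key=lambda s: s.A_tot)
    return states


def lpa_classify(fb: FeedbackParameters, total: float = 1.0,
                 depletion_level: float = 0.05,
                 t_relax: float = 400.0) -> RegimeLabel:
    """LPA regime classification.

    inducible_polarity requires (i) at least two coexisting stable local
    steady states and (ii) a transient set-to-low local perturbation of the
    membrane density relaxing to the low state while the uniform background
    state is itself stable.
    """
    try:
        states = local_steady_states(fb, total=total)
    except Exception as exc:  # root-finding failure -> indeterminate
        return RegimeLabel(label="indeterminate", message=str(exc))
    stable = [s for s in states if s.stable]
    out = RegimeLabel(label="no_polarity", states=states, n_stable=len(stable))
    if len(stable) < 2:
        return out
    C = total * (1.0 - fb.membrane_fraction)
    uniform = min(states, key=lambda s: abs(s.A_tot - fb.membrane_fraction * total))
    if not uniform.stable:
        out.message = "uniform state unstable"
        return out
    low = stable[0]
    y0 = depletion_level * uniform.A
    sol = solve_ivp(lambda _t, y: _local_rhs(y, fb, C), (0.0, t_relax), y0,
                    method="LSODA", rtol=1e-8, atol=1e-12)
    n = np.arange(1, fb.n_max + 1)
    A_end = float(np.dot(n, sol.y[:, -1]))
    relaxed_low = abs(A_end - low.A_tot) < 0.05 * max(low.A_tot, 1e-6) and \
        A_end < 0.5 * uniform.A_tot
    out.transition_ok = bool(relaxed_low)
    if relaxed_low:
        out.label = "inducible_polarity"
    return out


@dataclass
class PhaseDiagram:
    K_f_grid: np.ndarray
    K_P_grid: np.ndarray
    labels: np.ndarray           # (len(K_f_grid), len(K_P_grid)) of str
    regimes: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, kf in enumerate(self.K_f_grid):
            for j, kp in enumerate(self.K_P_grid):
                rows.append({"K_f": kf, "K_P": kp, "label": self.labels[i, j]})
        return pd.DataFrame(rows)


def phase_diagram(K_f_grid, K_P_grid, template: FeedbackParameters | None = None,
                  total: float = 1.0) -> PhaseDiagram:
    """Per-cell calibrate + LPA classification over a (K_f, K_P) grid.

    Indeterminate cells are flagged, never silently filled.
    """
    K_f_grid = np.asarray(K_f_grid, dtype=float)
    K_P_grid = np.asarray(K_P_grid, dtype=float)
    if np.any(np.diff(K_f_grid) <= 0) or np.any(np.diff(K_P_grid) <= 0):
        raise KineticsError("grids must be strictly increasing")
    base = template if template is not None else FeedbackParameters(K_f=0.0, K_P=0.0)
    labels = np.empty((len(K_f_grid), len(K_P_grid)), dtype=object)
    regimes = []
    for i, kf in enumerate(K_f_grid):
        for j, kp in enumerate(K_P_grid):
            fb = base.replace(K_f=float(kf), K_P=float(kp), K_on=None, A_sat=None)
            try:
                reg = lpa_classify(calibrate(fb, total=total), total=total)
            except ConvergenceError as exc:
                reg = RegimeLabel(label="indeterminate", message=str(exc))
            labels[i, j] = reg.label
            regimes.append(reg)
    return PhaseDiagram(K_f_grid=K_f_grid, K_P_grid=K_P_grid,
                        labels=labels, regimes=regimes)


# ---------------------------------------------------------------------------
# method-of-lines PDE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid1D:
    """1-D anterior-posterior axis; anterior is the left half."""

    length: float = 54.0
    n_cells: int = 108

    @property
    def dx(self) -> float:
        return self.length / self.n_cells

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx

    def halves(self, margin_um: float = 1.0):
        """Anterior/posterior index ranges, excluding a physical margin at
        the midline (2 grid cells on the default grid) so the asymmetry
        readout is independent of grid resolution."""
        mid = self.n_cells // 2
        m = max(1, round(margin_um / self.dx))
        return slice(0, mid - m), slice(mid + m, self.n_cells)


@dataclass
class FieldState:
    """Spatial state: per-size membrane profiles plus the cytoplasmic pool."""

    grid: Grid1D
    A: np.ndarray       # (n_max, n_cells), subunit-count-weighted by n when summed
    C: float
    t: float = 0.0

    @property
    def A_tot(self) -> np.ndarray:
        n = np.arange(1, self.A.shape[0] + 1)
        return n @ self.A

    @property
    def total(self) -> float:
        return float(self.A_tot.mean() + self.C)

    def asymmetry(self, margin_um: float = 1.0) -> float:
        ant, post = self.grid.halves(margin_um)
        a = self.A_tot
        return float(a[ant].mean() / a[post].mean())

    def mean_size(self, region: slice | None = None) -> float:
        A = self.A if region is None else self.A[:, region]
        n = np.arange(1, A.shape[0] + 1)
        tot = A.sum()
        return float((n @ A).sum() / tot) if tot > 0 else 1.0

    def scaled(self, factor: float) -> "FieldState":
        return FieldState(grid=self.grid, A=self.A * factor,
                          C=self.C * factor, t=self.t)


@dataclass
class MaintenanceResult:
    final: FieldState
    t_s: np.ndarray              # seconds
    anterior_mean: np.ndarray
    posterior_mean: np.ndarray
    asymmetry: float
    recruitment_ratio: float
    mean_size_anterior: float


def _pde_rhs(y: np.ndarray, fb: FeedbackParameters, grid: Grid1D,
             D_hat: float, bias: np.ndarray | None) -> np.ndarray:
    nmax, nc = fb.n_max, grid.n_cells
    A = y[:-1].reshape(nmax, nc)
    C = y[-1]
    n = np.arange(1, nmax + 1)[:, None]
    A_tot = (n * A).sum(axis=0)
    g = recruitment_rate(A_tot, fb, bias=bias) * C
    J = fb.K_P * A[0] * A[:-1] - A[1:]
    dA = np.empty_like(A)
    koff = fb.koff_hat[:, None]
    dA[0] = g - fb.koff_hat[0] * A[0] - 2.0 * J[0] - J[1:].sum(axis=0)
    dA[1:-1] = J[:-1] - J[1:] - koff[1:-1, 0][:, None] * A[1:-1]
    dA[-1] = J[-1] - fb.koff_hat[-1] * A[-1]
    if D_hat > 0:  # lateral diffusion of membrane monomers, no-flux ends
        lap = np.empty(nc)
        lap[1:-1] = A[0, :-2] - 2 * A[0, 1:-1] + A[0, 2:]
        lap[0] = A[0, 1] - A[0, 0]
        lap[-1] = A[0, -2] - A[0, -1]
        dA[0] += D_hat / grid.dx**2 * lap
    off = (n * A * fb.koff_hat[:, None]).sum(axis=0)
    dC = float((off - g).mean())
    return np.append(dA.ravel(), dC)


def simulate_maintenance(init: FieldState, fb: FeedbackParameters,
                         t_sim: float = 240.0, k_diss: float = DEFAULT_K_DISS,
                         D_m: float = 0.1, n_save: int = 49,
                         rtol: float = 1e-7, atol: float = 1e-11,
                         margin_um: float = 1.0) -> MaintenanceResult:
    """Integrate the spatial model for ``t_sim`` seconds and report readouts.

    Readouts: anterior/posterior asymmetry of subunit density, the
    anterior:posterior ratio of mean local recruitment rates, and the mean
    oligomer size on the anterior half (all excluding a small margin at the
    domain midpoint).
    """
    if fb.K_on is None:
        raise KineticsError("calibrate() first")
    grid = init.grid
    bias = fb.bias_profile
    if fb.bias_mode == "fixed_bias" and bias is None:
        raise KineticsError("fixed_bias mode requires a bias_profile")
    D_hat = D_m / k_diss
    tau_end = k_diss * t_sim
    y0 = np.append(init.A.ravel(), init.C)
    total0 = init.total
    t_eval = np.linspace(0.0, tau_end, n_save + 1)
    sol = solve_ivp(lambda _t, y: _pde_rhs(y, fb, grid, D_hat, bias),
                    (0.0, tau_end), y0, t_eval=t_eval, method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise ConvergenceError("PDE integration failed: " + sol.message)
    nmax, nc = fb.n_max, grid.n_cells
    ant, post = grid.halves(margin_um)
    n = np.arange(1, nmax + 1)
    ant_mean = np.empty(len(sol.t))
    post_mean = np.empty(len(sol.t))
    for i in range(len(sol.t)):
        a_tot = n @ sol.y[:-1, i].reshape(nmax, nc)
        ant_mean[i] = a_tot[ant].mean()
        post_mean[i] = a_tot[post].mean()
    A_end = np.clip(sol.y[:-1, -1].reshape(nmax, nc), 0.0, None)
    final = FieldState(grid=grid, A=A_end, C=float(sol.y[-1, -1]), t=t_sim)
    drift = abs(final.total - total0)
    if drift > 1e-6 * total0:
        raise ConvergenceError("mass conservation drift exceeds tolerance",
                               drift=drift, total=total0)
    a_tot_end = final.A_tot
    if fb.bias_mode == "fixed_bias":
        kon_field = fb.K_on * bias
    else:
        kon_field = recruitment_rate(a_tot_end, fb)
    rr = float(kon_field[ant].mean() / kon_field[post].mean())
    return MaintenanceResult(
        final=final, t_s=sol.t / k_diss,
        anterior_mean=ant_mean, posterior_mean=post_mean,
        asymmetry=float(a_tot_end[ant].mean() / a_tot_end[post].mean()),
        recruitment_ratio=rr,
        mean_size_anterior=final.mean_size(ant))


# ---------------------------------------------------------------------------
# controlled comparison and perturbation scenarios
# ---------------------------------------------------------------------------

def _match_fixed_bias(fb: FeedbackParameters, init: FieldState,
                      ref: MaintenanceResult, t_sim: float,
                      tol: float = 0.02, bias_ratio: float | None = None,
                      **sim_kw) -> FeedbackParameters:
    """Calibrate the fixed-bias variant to reproduce the feedback reference.

    With ``bias_ratio=None`` the bias profile takes the shape of the
    feedback model's final recruitment field (so the recruitment-ratio
    readout matches by construction); with an explicit ``bias_ratio`` (for
    example the measured monomer recruitment asymmetry) the profile is an
    anterior:posterior step at that ratio, and the recruitment-ratio
    readout equals the ratio itself.  A global gain is then adjusted so
    the end-of-run asymmetry matches, and the matched readouts are
    verified to ``tol``.
    """
    def run(prof: np.ndarray) -> MaintenanceResult:
        fbb = fb.replace(bias_mode="fixed_bias", bias_profile=prof)
        return simulate_maintenance(init, fbb, t_sim=t_sim, **sim_kw)

    if bias_ratio is None:
        # pointwise Picard iteration on the bias profile so the fixed-bias
        # run reproduces the feedback model's final density profile (the
        # "identical wild-type solution"); the density responds sublinearly
        # to recruitment, hence the damped exponent
        prof = 1.0 + fb.K_f * np.minimum(ref.final.A_tot, fb.A_sat)
        for _ in range(10):
            res = run(prof)
            ratio = ref.final.A_tot / np.clip(res.final.A_tot, 1e-12, None)
            if np.abs(ratio - 1.0).max() < 0.004:
                break
            prof = prof * ratio**0.7
        checks = {
            "asymmetry": (res.asymmetry, ref.asymmetry),
            "mean_size": (res.mean_size_anterior, ref.mean_size_anterior),
            "recruitment_ratio": (res.recruitment_ratio, ref.recruitment_ratio),
        }
    else:
        # prescribed anterior:posterior step contrast (e.g. the measured
        # monomer recruitment asymmetry); a single overall-gain knob is
        # left, matched on the end-of-run asymmetry
        nc = init.grid.n_cells
        shape = np.where(np.arange(nc) < nc // 2, float(bias_ratio), 1.0)

        def err(scale: float) -> float:
            return run(scale * shape).asymmetry - ref.asymmetry

        lo, hi = 0.3, 3.0
        if err(lo) * err(hi) < 0:
            scale = brentq(err, lo, hi, xtol=1e-4)
        else:
            scale = min((lo, hi, 1.0), key=lambda s: abs(err(s)))
        prof = scale * shape
        res = run(prof)
        checks = {"asymmetry": (res.asymmetry, ref.asymmetry)}
    for name, (got, want) in checks.items():
        if abs(got - want) > tol * abs(want):
            raise CalibrationMismatch(
                f"fixed-bias calibration mismatch on {name}: {got:.4g} vs {want:.4g}")
    return fb.replace(bias_mode="fixed_bias", bias_profile=prof)


def _reequilibrated(init: FieldState, fb: FeedbackParameters,
                    factor: float) -> FieldState:
    """Scale a profile to a depleted total with re-equilibrated composition.

    Depleted embryos develop at the lower density, so each point carries the
    local geometric size composition of its scaled density rather than the
    scaled wild-type composition.
    """
    from .kinetics import steady_state_alpha
    a_tot = init.A_tot * factor
    nmax = fb.n_max
    n = np.arange(1, nmax + 1)[:, None]
    alpha = np.array([steady_state_alpha(fb.K_P * a) for a in a_tot])
    A1 = a_tot * (1.0 - alpha) ** 2
    A = A1[None, :] * alpha[None, :] ** (n - 1)
    subunits = (n * A).sum(axis=0)
    scale = np.divide(a_tot, subunits, out=np.zeros_like(a_tot),
                      where=subunits > 0)
    return FieldState(grid=init.grid, A=A * scale[None, :],
                      C=init.C * factor, t=0.0)


def depletion_response(fb: FeedbackParameters, init: FieldState,
                       totals: np.ndarray, t_sim: float = 240.0,
                       match_tol: float = 0.02, bias_ratio: float | None = None,
                       rescale: str = "equilibrate", **sim_kw):
    """Mathematically controlled comparison: feedback vs fixed recruitment bias.

    Runs the reference (total = 1) feedback simulation, calibrates a
    fixed-bias variant to the same 240-s readouts, then scans total PAR-3
    downward, scaling the polarized initial profile with the total.  Returns
    a DataFrame of (total, variant, asymmetry, mean_size, recruitment_ratio).
    """
    import pandas as pd
    totals = np.asarray(totals, dtype=float)
    if np.any(np.diff(totals) > 0):
        raise KineticsError("totals must be scanned in descending order")
    ref = simulate_maintenance(init, fb, t_sim=t_sim, **sim_kw)
    fb_bias = _match_fixed_bias(fb, init, ref, t_sim, tol=match_tol,
                                bias_ratio=bias_ratio, **sim_kw)
    if rescale not in ("equilibrate", "linear"):
        raise KineticsError(f"unknown rescale mode {rescale!r}")
    rows = []
    for T in totals:
        scaled = (_reequilibrated(init, fb, T) if rescale == "equilibrate"
                  else init.scaled(T))
        for name, p in (("feedback", fb), ("fixed_bias", fb_bias)):
            res = simulate_maintenance(scaled, p, t_sim=t_sim, **sim_kw)
            rows.append({"total": T, "variant": name,
                         "asymmetry": res.asymmetry,
                         "mean_size": res.mean_size_anterior,
                         "recruitment_ratio": res.recruitment_ratio})
    return pd.DataFrame(rows)


def _scenario_control(fb):
    return fb


def _scenario_no_feedback(fb):
    # acute loss of recruitment feedback (par-6/mrck-1 co-depletion mimic):
    # K_f -> 0 without recalibrating basal recruitment
    return fb.replace(K_f=0.0)


def _scenario_cdc42(fb):
    # CDC-42 loss raises basal recruitment: doubling k_basal while holding
    # k_f = K_on*K_f constant (the calibrated control is the 50%-reduced basal)
    return fb.replace(K_on=2.0 * fb.K_on, K_f=0.5 * fb.K_f)


def _scenario_basal_50(fb):
    return fb.replace(K_on=0.5 * fb.K_on, K_f=2.0 * fb.K_f)


PERTURBATION_SCENARIOS = {
    "control": _scenario_control,
    "no_feedback": _scenario_no_feedback,
    "cdc42_mimic": _scenario_cdc42,
    "basal_50pct": _scenario_basal_50,
}


def perturbation_scenarios(fb: FeedbackParameters, scenario: str,
                           init: FieldState, t_sim: float = 240.0,
                           **sim_kw) -> MaintenanceResult:
    """Named parameter perturbations simulated from a polarized initial state."""
    try:
        edit = PERTURBATION_SCENARIOS[scenario]
    except KeyError:
        raise KineticsError(
            f"unknown scenario {scenario!r}; choose from {sorted(PERTURBATION_SCENARIOS)}")
    return simulate_maintenance(init, edit(fb), t_sim=t_sim, **sim_kw)
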