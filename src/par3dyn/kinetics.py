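"""Well-mixed, size-structured kinetics of PAR-3 membrane binding and oligomerization.

The model: cytoplasmic monomers bind the membrane with flux ``k_on``
(molecules um^-2 s^-1) and unbind with rate ``k_off(1)``; membrane-bound
monomers add to (and leave) oligomer termini with rate constants ``k_ass``
(um^2 s^-1) and ``k_diss`` (s^-1), defining a self-affinity
``K_P = k_ass / k_diss`` (um^2); whole oligomers of size n detach with a
size-dependent rate ``k_off(n)`` that decays sharply with n (binding
avidity).  Direct binding of cytoplasmic monomers to oligomers and membrane
binding of preformed oligomers are neglected.

When monomer-oligomer exchange is fast relative to oligomer detachment, the
steady-state size distribution is geometric, ``A_n = A_1 * alpha**(n-1)``
with ``alpha = K_P * A_1``, and closed forms link alpha, the mean oligomer
size ``s = 1/(1-alpha)`` and the total subunit density ``A_tot`` through the
single dimensionless product ``x = A_tot * K_P``.

Units are fixed package-wide: um, s, molecules um^-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded
from scipy.optimize import brentq

__all__ = [
    "RateParameters",
    "SizeDistribution",
    "SteadyStateSummary",
    "KineticsError",
    "ConvergenceError",
    "default_koff_table",
    "steady_state_alpha",
    "mean_size",
    "geometric_distribution",
    "effective_dissociation_rate",
    "steady_state_density",
    "becker_doring_profile",
    "solve_a1_for_total",
    "steady_state_exact",
    "integrate_well_mixed",
    "gillespie_well_mixed",
    "terminal_fraction",
    "predict_frap",
]

#: clip densities in [-NEG_TOL, 0) to zero; larger negatives are errors
NEG_TOL = 1e-9


class KineticsError(ValueError):
    """Domain or state error in the kinetic model."""


class ConvergenceError(RuntimeError):
    """A fixed-point or root search failed; carries diagnostics."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


def default_koff_table(n_max: int, k1: float = 2.7, k2: float = 0.8,
                       k3: float = 0.2) -> np.ndarray:
    """Default size-dependent membrane detachment rates (s^-1).

    k_off(1) = 2.7 s^-1 as measured; a smooth monotone decay through sizes 2
    and 3; zero beyond size 3, where oligomer detachment is negligible.
    The intermediate values are configuration, not constants -- quantitative
    runs should supply measured values.
    """
    k = np.zeros(n_max)
    k[0] = k1
    if n_max >= 2:
        k[1] = k2
    if n_max >= 3:
        k[2] = k3
    return k


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rate constants for the well-mixed size-structured model.

    Attributes
    ----------
    k_on : monomer membrane recruitment flux, molecules um^-2 s^-1.
    k_off_by_size : array of k_off(n) for n = 1..n_max, s^-1.
    k_ass : monomer-terminus association rate constant, um^2 s^-1.
    k_diss : terminal-subunit dissociation rate, s^-1.
    n_max : size truncation (>= 3).
    """

    k_on: float
    k_off_by_size: np.ndarray
    k_ass: float
    k_diss: float
    n_max: int = 50

    def __post_init__(self):
        koff = np.asarray(self.k_off_by_size, dtype=float)
        object.__setattr__(self, "k_off_by_size", koff)
        if self.n_max < 3:
            raise KineticsError("n_max must be >= 3")
        if koff.shape != (self.n_max,):
            raise KineticsError(
                f"k_off_by_size must have length n_max={self.n_max}, got {koff.shape}")
        if self.k_on < 0 or self.k_ass < 0 or self.k_diss < 0 or np.any(koff < 0):
            raise KineticsError("all rates must be >= 0")

    @property
    def K_P(self) -> float:
        """Self-affinity k_ass / k_diss (um^2)."""
        if self.k_diss == 0:
            raise KineticsError("K_P undefined for k_diss = 0")
        return self.k_ass / self.k_diss

    @classmethod
    def defaults(cls, k_on: float = 0.5, k_diss: float = 0.08,
                 K_P: float = 1.0, n_max: int = 50) -> "RateParameters":
        return cls(k_on=k_on, k_off_by_size=default_koff_table(n_max),
                   k_ass=K_P * k_diss, k_diss=k_diss, n_max=n_max)


@dataclass
class SizeDistribution:
    """Per-size membrane oligomer densities A_n (oligomers um^-2), n = 1..n_max."""

    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if np.any(A < -NEG_TOL):
            raise KineticsError(f"negative density beyond tolerance: min={A.min()}")
        self.A = np.clip(A, 0.0, None)

    @property
    def n(self) -> np.ndarray:
        return np.arange(1, len(self.A) + 1)

    @property
    def A_tot(self) -> float:
        """Total subunit density sum(n * A_n)."""
        return float(np.dot(self.n, self.A))

    @property
    def oligomer_density(self) -> float:
        return float(self.A.sum())

    @property
    def s(self) -> float:
        """Mean oligomer size sum(n A_n) / sum(A_n)."""
        tot = self.A.sum()
        if tot == 0:
            return 1.0
        return self.A_tot / tot

    @property
    def alpha(self) -> float:
        """Oligomerization strength implied by the mean size, alpha = 1 - 1/s.

        Exact for a geometric distribution; a summary statistic otherwise.
        """
        return 1.0 - 1.0 / self.s

    def oligomers_only(self) -> "SizeDistribution":
        """The same distribution with the monomer class removed (n >= 2)."""
        A = self.A.copy()
        A[0] = 0.0
        return SizeDistribution(A)


@dataclass(frozen=True)
class SteadyStateSummary:
    alpha: float
    s: float
    A_tot: float
    A_1: float
    k_eff: float
    P: float


def steady_state_alpha(x):
    """Oligomerization strength alpha as a function of x = A_tot * K_P.

    alpha = (1 + 2x - sqrt(1 + 4x)) / (2x), the unique root in [0, 1) of
    alpha = x (1 - alpha)^2.  Continuous at x -> 0 (alpha -> x).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise KineticsError("x = A_tot * K_P must be >= 0")
    small = x_arr < 1e-5
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = (1.0 + 2.0 * x_arr - np.sqrt(1.0 + 4.0 * x_arr)) / (2.0 * x_arr)
    series = x_arr - 2.0 * x_arr**2 + 5.0 * x_arr**3
    out = np.where(small, series, exact)
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def mean_size(alpha):
    """Mean oligomer size s = 1 / (1 - alpha), for 0 <= alpha < 1."""
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a >= 1):
        raise KineticsError("alpha must lie in [0, 1)")
    out = 1.0 / (1.0 - a)
    return out.item() if np.isscalar(alpha) or a.ndim == 0 else out


def geometric_distribution(A_1: float, alpha: float, n_max: int) -> SizeDistribution:
    """Geometric size distribution A_n = A_1 * alpha**(n-1)."""
    if A_1 < 0:
        raise KineticsError("A_1 must be >= 0")
    if not (0 <= alpha < 1):
        raise KineticsError("alpha must lie in [0, 1)")
    n = np.arange(n_max)
    return SizeDistribution(A_1 * alpha**n)


def effective_dissociation_rate(dist: SizeDistribution,
                                k_off_by_size: np.ndarray) -> float:
    """Subunit-weighted mean detachment rate k_eff = sum(n k_off(n) A_n) / sum(n A_n)."""
    koff = np.asarray(k_off_by_size, dtype=float)
    if koff.shape != dist.A.shape:
        raise KineticsError("k_off_by_size length must match distribution")
    w = dist.n * dist.A
    denom = w.sum()
    if denom <= 0:
        raise KineticsError("k_eff undefined for A_tot = 0")
    return float(np.dot(w, koff) / denom)


def _geometric_off_flux_of_alpha(alpha: float, koff: np.ndarray, K_P: float) -> float:
    # total off-flux sum(n koff(n) A_n) on the geometric distribution,
    # using A_1 alpha**(n-1) = alpha**n / K_P
    n = np.arange(1, len(koff) + 1)
    return float(np.sum(n * koff * alpha**n) / K_P)


def steady_state_density(k_on: float, params: RateParameters,
                         rtol: float = 1e-10) -> SteadyStateSummary:
    """Self-consistent steady-state density under the geometric closure.

    Solves P = k_on / k_eff(P) where k_eff is evaluated on the geometric
    distribution implied by alpha(P * K_P).  Valid when monomer-oligomer
    exchange is fast relative to detachment.
    """
    koff = params.k_off_by_size
    diffs = np.diff(koff)
    if np.any(diffs > 1e-12):
        warnings.warn("k_off_by_size is not monotone non-increasing", stacklevel=2)
    if k_on == 0:
        return SteadyStateSummary(alpha=0.0, s=1.0, A_tot=0.0, A_1=0.0,
                                  k_eff=float(koff[0]), P=0.0)
    K_P = params.K_P
    if K_P == 0:
        P = k_on / koff[0]
        return SteadyStateSummary(alpha=0.0, s=1.0, A_tot=P, A_1=P,
                                  k_eff=float(koff[0]), P=P)
    # total off-flux is monotone increasing in alpha; solve flux(alpha) = k_on
    sup = _geometric_off_flux_of_alpha(1.0 - 1e-14, koff, K_P)
    if k_on >= sup:
        raise ConvergenceError(
            "no steady state: k_on exceeds the maximal detachment flux",
            k_on=k_on, max_flux=sup)
    alpha = brentq(lambda a: _geometric_off_flux_of_alpha(a, koff, K_P) - k_on,
                   0.0, 1.0 - 1e-14, xtol=1e-15, rtol=8.9e-16)
    A_1 = alpha / K_P
    dist = geometric_distribution(A_1, alpha, params.n_max)
    # P from the truncated distribution so that P * k_eff = k_on exactly
    P = dist.A_tot
    k_eff = effective_dissociation_rate(dist, koff)
    if alpha ** params.n_max > 1e-6:
        warnings.warn("geometric tail mass exceeds 1e-6 of A_1; increase "
                      "n_max", stacklevel=2)
    if abs(P * k_eff - k_on) > max(rtol * k_on, 1e-12):
        raise ConvergenceError("steady-state self-consistency failed",
                               residual=P * k_eff - k_on)
    return SteadyStateSummary(alpha=float(alpha), s=dist.s,
                              A_tot=P, A_1=A_1, k_eff=k_eff, P=P)


# ---------------------------------------------------------------------------
# exact truncated Becker-Doring steady state
# ---------------------------------------------------------------------------

def becker_doring_profile(A_1: float, params: RateParameters) -> SizeDistribution:
    """Exact steady-state distribution of the truncated system given A_1.

    At steady state the oligomer balance for n >= 2 is linear tridiagonal in
    (A_2..A_n_max) once A_1 is fixed:
        J_{n-1} - J_n - koff(n) A_n = 0,  J_n = k_ass A_1 A_n - k_diss A_{n+1}.
    """
    nmax = params.n_max
    koff = params.k_off_by_size
    ka1 = params.k_ass * A_1
    kd = params.k_diss
    m = nmax - 1  # unknowns A_2..A_nmax
    if m == 0 or A_1 == 0:
        A = np.zeros(nmax)
        A[0] = A_1
        return SizeDistribution(A)
    # rows i=0..m-1 correspond to sizes n=i+2
    ab = np.zeros((3, m))
    rhs = np.zeros(m)
    for i in range(m):
        n = i + 2
        # J_{n-1} = ka1*A_{n-1} - kd*A_n ; J_n = ka1*A_n - kd*A_{n+1} (0 at top)
        diag = -kd - koff[n - 1]
        if n < nmax:
            diag -= ka1
            ab[0, i + 1] = kd       # coefficient of A_{n+1}
        if i == 0:
            rhs[i] = -ka1 * A_1     # A_{n-1} = A_1 known
        else:
            ab[2, i - 1] = ka1      # coefficient of A_{n-1}
        ab[1, i] = diag
    sol = solve_banded((1, 1), ab, rhs)
    A = np.empty(nmax)
    A[0] = A_1
    A[1:] = np.clip(sol, 0.0, None)
    return SizeDistribution(A)


def _grow_bracket(fn, target, hi0, grow: float = 1.5, max_iter: int = 400):
    """Smallest hi with fn(hi) >= target, growing geometrically from hi0.

    Guards against overflow/singularity of the tridiagonal solve at very
    large monomer densities (effective growth ratio K_P*A_1 >> 1).
    """
    hi = hi0
    last_good = None
    for _ in range(max_iter):
        try:
            val = fn(hi)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            if last_good is None:
                hi *= 0.5
                continue
            raise ConvergenceError(
                "steady-state solve overflowed before reaching the target",
                target=target, last_value=fn(last_good))
        if val >= target:
            return hi
        last_good = hi
        hi *= grow
    raise ConvergenceError("no steady state: flux saturates below the target",
                           target=target, last_value=val)


def solve_a1_for_total(params: RateParameters, A_target: float) -> float:
    """Monomer density A_1 of the exact steady profile with subunit total A_target."""
    if A_target == 0:
        return 0.0
    K_P = params.K_P if params.k_diss > 0 else 0.0

    def total(a1):
        return becker_doring_profile(a1, params).A_tot

    hi0 = A_target if K_P == 0 else min(A_target, 1.0 / K_P)
    hi = _grow_bracket(total, A_target, hi0)
    return brentq(lambda a: total(a) - A_target, 0.0, hi,
                  xtol=1e-300, rtol=8.9e-16)


def steady_state_exact(k_on: float, params: RateParameters,
                       A1_hi: float | None = None) -> SteadyStateSummary:
    """Steady state of the truncated Becker-Doring system (no closure).

    Finds A_1 such that the total detachment flux sum(n koff(n) A_n) balances
    the recruitment flux k_on.
    """
    koff = params.k_off_by_size
    if k_on == 0:
        return SteadyStateSummary(alpha=0.0, s=1.0, A_tot=0.0, A_1=0.0,
                                  k_eff=float(koff[0]), P=0.0)

    def flux(A_1):
        d = becker_doring_profile(A_1, params)
        return float(np.dot(d.n * d.A, koff))

    K_P = params.K_P if params.k_diss > 0 else 0.0
    hi0 = k_on / max(koff[0], 1e-30)
    if K_P > 0:
        hi0 = min(hi0, 1.0 / K_P)
    hi = _grow_bracket(flux, k_on, max(hi0, 1e-12))
    A_1 = brentq(lambda a: flux(a) - k_on, 0.0, hi, xtol=1e-300, rtol=8.9e-16)
    dist = becker_doring_profile(A_1, params)
    k_eff = effective_dissociation_rate(dist, koff)
    return SteadyStateSummary(alpha=dist.alpha, s=dist.s, A_tot=dist.A_tot,
                              A_1=A_1, k_eff=k_eff, P=dist.A_tot)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def becker_doring_rhs(A: np.ndarray, k_on, koff, k_ass, k_diss) -> np.ndarray:
    """Time derivative of the size-structured densities (vectorized).

    dA_1/dt = k_on - koff(1) A_1 - 2 J_1 - sum_{n>=2} J_n
    dA_n/dt = J_{n-1} - J_n - koff(n) A_n          (J_{n_max} = 0)
    with J_n = k_ass A_1 A_n - k_diss A_{n+1}.
    """
    J = k_ass * A[0] * A[:-1] - k_diss * A[1:]
    dA = np.empty_like(A)
    dA[0] = k_on - koff[0] * A[0] - 2.0 * J[0] - J[1:].sum()
    dA[1:-1] = J[:-1] - J[1:] - koff[1:-1] * A[1:-1]
    dA[-1] = J[-1] - koff[-1] * A[-1]
    return dA


@dataclass
class WellMixedTrajectory:
    t: np.ndarray
    A: np.ndarray               # shape (n_times, n_max)
    params: RateParameters
    mass_residual: np.ndarray   # A_tot(t) - A_tot(0) - int(k_on - offflux) dt

    def distribution(self, i: int) -> SizeDistribution:
        return SizeDistribution(self.A[i])

    @property
    def A_tot(self) -> np.ndarray:
        n = np.arange(1, self.A.shape[1] + 1)
        return self.A @ n


def integrate_well_mixed(params: RateParameters, init: SizeDistribution,
                         t_grid: np.ndarray, rtol: float = 1e-8,
                         atol: float = 1e-12) -> WellMixedTrajectory:
    """Integrate the well-mixed size-structured ODE on t_grid (stiff-safe).

    An auxiliary state accumulates the net boundary flux
    int (k_on - sum n koff(n) A_n) dt so the subunit balance law can be
    checked exactly against the integrator output.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    nmax = params.n_max
    if len(init.A) != nmax:
        raise KineticsError("init distribution length must equal n_max")
    koff = params.k_off_by_size
    n_vec = np.arange(1, nmax + 1)

    def rhs(_t, y):
        A = y[:nmax]
        dA = becker_doring_rhs(A, params.k_on, koff, params.k_ass, params.k_diss)
        dflux = params.k_on - float(np.dot(n_vec * A, koff))
        return np.append(dA, dflux)

    y0 = np.append(init.A, 0.0)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise ConvergenceError("ODE integration failed: " + sol.message)
    A = sol.y[:nmax].T
    if np.any(A < -NEG_TOL):
        raise ConvergenceError("integration produced negative densities",
                               min_density=float(A.min()))
    A = np.clip(A, 0.0, None)
    a_tot = A @ n_vec
    residual = a_tot - a_tot[0] - sol.y[nmax]
    return WellMixedTrajectory(t=sol.t, A=A, params=params, mass_residual=residual)


def terminal_fraction(dist: SizeDistribution) -> float:
    """Fraction of subunits that are terminal, with min(n, 2) termini per n-mer.

    For the geometric distribution this is 1 - alpha^2; restricted to
    oligomers (n >= 2, via dist.oligomers_only()) it is 2(1-alpha)/(2-alpha),
    which evaluates to 0.43 at alpha = 0.730.
    """
    w = dist.n * dist.A
    denom = w.sum()
    if denom <= 0:
        raise KineticsError("terminal fraction undefined for empty distribution")
    term = np.minimum(dist.n, 2) * dist.A
    return float(term.sum() / denom)


def predict_frap(dist: SizeDistribution, k_diss: float,
                 k_off_by_size: np.ndarray | None = None) -> tuple[float, float]:
    """FRAP prediction on intermediate timescales: exchange of terminal subunits.

    Returns (half_time, plateau_fraction) with half_time = ln(2)/k_diss and
    plateau = terminal_fraction(dist).  Valid when monomer unbinding is fast
    and whole-oligomer turnover slow relative to k_diss; a warning is issued
    when k_off(1) does not dominate k_diss.
    """
    if k_diss <= 0:
        raise KineticsError("k_diss must be > 0")
    if k_off_by_size is not None and k_off_by_size[0] < 5 * k_diss:
        warnings.warn("k_off(1) is not >> k_diss; intermediate-timescale "
                      "approximation may be poor", stacklevel=2)
    return float(np.log(2.0) / k_diss), terminal_fraction(dist)


# ---------------------------------------------------------------------------
# Gillespie oracle
# ---------------------------------------------------------------------------

@dataclass
class GillespieResult:
    """Exact SSA trajectory summary over a finite membrane patch."""

    t_end: float
    area: float
    events: np.ndarray           # (n_events, 2): time, reaction code
    final_counts: np.ndarray     # N_n at t_end
    mean_counts: np.ndarray      # time-averaged N_n over [t_burn, t_end]
    batch_means: np.ndarray      # (n_batches, n_max) time-averaged per batch
    n_events: int = field(init=False)

    def __post_init__(self):
        self.n_events = len(self.events)

    def _stats(self, counts: np.ndarray) -> tuple[float, float]:
        n = np.arange(1, len(counts) + 1)
        tot = counts.sum()
        if tot == 0:
            return 1.0, 0.0
        s = float(np.dot(n, counts) / tot)
        return s, 1.0 - 1.0 / s

    @property
    def mean_s(self) -> float:
        return self._stats(self.mean_counts)[0]

    @property
    def mean_alpha(self) -> float:
        return self._stats(self.mean_counts)[1]

    def alpha_se(self) -> float:
        """Monte-Carlo standard error of alpha from batch means."""
        alphas = np.array([self._stats(b)[1] for b in self.batch_means])
        return float(alphas.std(ddof=1) / np.sqrt(len(alphas)))

    def s_se(self) -> float:
        svals = np.array([self._stats(b)[0] for b in self.batch_means])
        return float(svals.std(ddof=1) / np.sqrt(len(svals)))


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _ssa_core(N, koff, k_on, k_ass, k_diss, area, t_end, t_burn,
              edges, acc, ev_t, ev_code, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    nmax = N.shape[0]
    n_batches = acc.shape[0]
    max_events = ev_t.shape[0]
    a_bind = k_on * area
    t = 0.0
    n_ev = 0
    while t < t_end and n_ev < max_events:
        total = a_bind
        for n in range(nmax):
            total += koff[n] * N[n]
        if k_ass > 0.0 and N[0] > 0:
            total += k_ass * N[0] * (N[0] - 1) / area
            for n in range(1, nmax - 1):
                total += k_ass * N[0] * N[n] / area
        for n in range(1, nmax):
            total += k_diss * N[n]
        if total <= 0.0:
            t_new = t_end
        else:
            t_new = t - np.log(np.random.random()) / total
            if t_new > t_end:
                t_new = t_end
        # accumulate time-weighted counts over [t, t_new)
        if t_new > t_burn:
            lo = t if t > t_burn else t_burn
            for i in range(n_batches):
                a = lo if lo > edges[i] else edges[i]
                b = t_new if t_new < edges[i + 1] else edges[i + 1]
                if b > a:
                    w = b - a
                    for n in range(nmax):
                        acc[i, n] += w * N[n]
        t = t_new
        if t >= t_end or total <= 0.0:
            break
        u = np.random.random() * total
        if u < a_bind:
            N[0] += 1
            ev_t[n_ev] = t
            ev_code[n_ev] = 0
            n_ev += 1
            continue
        u -= a_bind
        chosen = False
        for n in range(nmax):
            u -= koff[n] * N[n]
            if u < 0.0:
                N[n] -= 1
                ev_t[n_ev] = t
                ev_code[n_ev] = 100 + n + 1
                n_ev += 1
                chosen = True
                break
        if chosen:
            continue
        if k_ass > 0.0 and N[0] > 0:
            u -= k_ass * N[0] * (N[0] - 1) / area
            if u < 0.0:
                N[0] -= 2
                N[1] += 1
                ev_t[n_ev] = t
                ev_code[n_ev] = 201
                n_ev += 1
                continue
            for n in range(1, nmax - 1):
                u -= k_ass * N[0] * N[n] / area
                if u < 0.0:
                    N[0] -= 1
                    N[n] -= 1
                    N[n + 1] += 1
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 200 + n + 1
                    n_ev += 1
                    chosen = True
                    break
            if chosen:
                continue
        for n in range(1, nmax):
            u -= k_diss * N[n]
            if u < 0.0:
                N[n] -= 1
                N[n - 1] += 1
                N[0] += 1
                ev_t[n_ev] = t
                ev_code[n_ev] = 300 + n + 1
                n_ev += 1
                break
    return n_ev


def gillespie_well_mixed(params: RateParameters, area: float,
                         init: SizeDistribution, t_end: float, seed: int,
                         t_burn: float = 0.0, n_batches: int = 20,
                         max_events: int = 5_000_000) -> GillespieResult:
    """Exact stochastic simulation of {bind, unbind(n), associate, dissociate}.

    Densities convert to counts via the patch area.  Deterministic for a
    fixed seed.  Zero total propensity is absorbing quiescence until t_end.
    Batch means over [t_burn, t_end] provide Monte-Carlo standard errors;
    choose batch widths comfortably above the slowest relaxation time
    (typically 1/min positive k_off) or the errors are underestimated.
    """
    if not np.isfinite(area) or area <= 0:
        raise KineticsError("area must be finite and > 0")
    nmax = params.n_max
    koff = np.ascontiguousarray(params.k_off_by_size, dtype=np.float64)
    N = np.rint(init.A * area).astype(np.int64)
    edges = np.linspace(t_burn, t_end, n_batches + 1)
    acc = np.zeros((n_batches, nmax))
    ev_t = np.empty(max_events)
    ev_code = np.empty(max_events, dtype=np.int64)
    n_ev = _ssa_core(N, koff, float(params.k_on), float(params.k_ass),
                     float(params.k_diss), float(area), float(t_end),
                     float(t_burn), edges, acc, ev_t, ev_code,
                     int(seed) % (2**31))
    widths = np.diff(edges)
    mean_counts = acc.sum(axis=0) / max(t_end - t_burn, 1e-300)
    batch_means = acc / widths[:, None]
    ev = np.column_stack([ev_t[:n_ev], ev_code[:n_ev].astype(float)])
    return GillespieResult(t_end=t_end, area=area, events=ev,
                           final_counts=N, mean_counts=mean_counts,
                           batch_means=batch_means)
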