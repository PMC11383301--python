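"""Inference of binding, unbinding and mobility parameters from particle tracks.

The estimators mirror standard single-molecule residence-time analysis:
release curves (survival-style cumulative lifetime histograms), exponential
mixture fits, photobleaching correction through a duty-ratio regression
(k_loss = k_app + k_pb * dr), recruitment ratios from extrapolated
zero-crossings, size-resolved dissociation rates from 1-s survival
fractions, and decomposition of 100-ms displacement distributions into
diffusive and cortex-bound components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls

__all__ = [
    "TrajectorySet",
    "ReleaseCurve",
    "ExponentialFit",
    "RateEstimates",
    "MobilityDistribution",
    "D100_BIN_EDGES",
    "build_release_curve",
    "fit_release",
    "photobleach_regression",
    "correct_rates",
    "recruitment_ratio",
    "bootstrap_recruitment_ratio",
    "size_dependent_koff",
    "d100_distribution",
    "d100_mixture",
    "brownian_reference",
    "confined_reference",
]

#: package-wide displacement histogram bins: 0 to 1.5 um in 50-nm steps
D100_BIN_EDGES = np.round(np.arange(0.0, 1.5 + 1e-9, 0.05), 10)


@dataclass
class TrajectorySet:
    """Single-particle trajectories plus per-track summaries.

    samples: tidy frame-level table (track_id, roi, frame, t_s, x_um, y_um,
    intensity_au).  tracks: one row per track with lifetime (s), censored
    flag and, when known from the generator, the true oligomer size.
    """

    samples: pd.DataFrame
    tracks: pd.DataFrame
    frame_interval: float = 0.05
    roi_areas: dict = field(default_factory=dict)
    duration: float = np.nan
    truth: dict = field(default_factory=dict)

    def lifetimes(self, roi: str | None = None,
                  drop_censored: bool = True) -> np.ndarray:
        t = self.tracks
        if roi is not None:
            t = t[t.roi == roi]
        if drop_censored and "censored" in t:
            t = t[~t.censored]
        return t.lifetime.to_numpy()

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, frame_interval: float = 0.05,
                     **kw) -> "TrajectorySet":
        g = samples.groupby("track_id")
        tracks = pd.DataFrame({
            "roi": g.roi.first(),
            "lifetime": (g.frame.max() - g.frame.min() + 1) * frame_interval,
            "censored": False,
        }).reset_index()
        return cls(samples=samples, tracks=tracks,
                   frame_interval=frame_interval, **kw)


@dataclass
class ReleaseCurve:
    """H(tau) = number of trajectories with lifetime > tau (survival counts)."""

    tau: np.ndarray
    H: np.ndarray
    roi: str = "whole"
    area: float = np.nan
    duration: float = np.nan
    n_excluded_short: int = 0
    n_censored: int = 0

    def __post_init__(self):
        if len(self.H) and np.any(np.diff(self.H) > 0):
            raise ValueError("release curve must be non-increasing")

    @property
    def empty(self) -> bool:
        return len(self.H) == 0 or self.H[0] == 0


def build_release_curve(lifetimes, tau_min: float = 0.2, frame: float = 0.05,
                        roi: str = "whole", area: float = np.nan,
                        duration: float = np.nan,
                        n_censored: int = 0) -> ReleaseCurve:
    """Cumulative survival histogram on the grid tau_n = n * frame.

    Trajectories shorter than ``tau_min`` (false-positive guard) are
    excluded entirely; an empty result is flagged through ``.empty``.
    """
    life = np.asarray(lifetimes, dtype=float)
    short = life < tau_min
    life = life[~short]
    if len(life) == 0:
        return ReleaseCurve(tau=np.array([]), H=np.array([]), roi=roi,
                            area=area, duration=duration,
                            n_excluded_short=int(short.sum()),
                            n_censored=n_censored)
    n_top = int(np.ceil(life.max() / frame)) + 1
    tau = frame * np.arange(1, n_top + 1)
    H = (life[None, :] > tau[:, None]).sum(axis=1)
    return ReleaseCurve(tau=tau, H=H.astype(float), roi=roi, area=area,
                        duration=duration, n_excluded_short=int(short.sum()),
                        n_censored=n_censored)


@dataclass
class ExponentialFit:
    """Fit of H(tau) ~ N * F(tau), F = lam e^{-k1 tau} + (1-lam) e^{-k2 tau}."""

    model: str                  # single | double
    N: float                    # extrapolated F(tau = 0) count
    lam: float
    k1: float
    k2: float | None
    tau_min_fit: float
    redchi: float = np.nan
    r_squared: float = np.nan
    success: bool = True
    at_bound: bool = False

    @property
    def rates_sorted(self) -> tuple[float, float]:
        """(fast, slow) raw rates before photobleach correction."""
        if self.model == "single":
            return self.k1, self.k1
        return max(self.k1, self.k2), min(self.k1, self.k2)

    def F(self, tau):
        tau = np.asarray(tau, dtype=float)
        if self.model == "single":
            return np.exp(-self.k1 * tau)
        return self.lam * np.exp(-self.k1 * tau) + (1 - self.lam) * np.exp(-self.k2 * tau)


def _loglinear_slope(tau, H):
    good = H > 0
    if good.sum() < 2:
        return 1.0, H.max() if len(H) else 1.0
    b, a = np.polyfit(tau[good], np.log(H[good]), 1)
    return max(-b, 1e-6), np.exp(a)


def fit_release(curve: ReleaseCurve, model: str = "double",
                tau_min_fit: float = 0.2) -> ExponentialFit:
    """Nonlinear least squares of the exponential-mixture survival model.

    Fits on tau >= tau_min_fit; reports N = extrapolated count at tau = 0
    (the release curve's zero-crossing) plus goodness diagnostics; flags
    non-convergence or parameters pinned at a bound.
    """
    sel = curve.tau >= tau_min_fit - 1e-12
    tau, H = curve.tau[sel], curve.H[sel]
    if (H > 0).sum() < (10 if model == "double" else 3):
        raise ValueError("too few nonzero release-curve points beyond tau_min_fit")
    k0, a0 = _loglinear_slope(tau, H)
    w = 1.0 / np.sqrt(H + 1.0)
    if model == "single":
        p = lmfit.Parameters()
        p.add("N", value=a0, min=0)
        p.add("k1", value=k0, min=1e-6)
        def resid(p):
            return (p["N"] * np.exp(-p["k1"] * tau) - H) / w
        out = lmfit.minimize(resid, p)
        fit = ExponentialFit(model="single", N=out.params["N"].value, lam=1.0,
                             k1=out.params["k1"].value, k2=None,
                             tau_min_fit=tau_min_fit, redchi=out.redchi,
                             success=out.success)
    else:
        # tail slope for the slow rate, early slope for the fast rate
        n_tail = max(len(tau) // 3, 2)
        k_slow0, a_tail = _loglinear_slope(tau[-n_tail:], H[-n_tail:])
        k_fast0, _ = _loglinear_slope(tau[: max(len(tau) // 4, 3)],
                                      H[: max(len(tau) // 4, 3)])
        k_fast0 = max(k_fast0, 2.0 * k_slow0)
        p = lmfit.Parameters()
        p.add("N", value=max(a0, H[0] * np.exp(k0 * tau[0])), min=0)
        p.add("lam", value=0.6, min=0.0, max=1.0)
        p.add("k1", value=k_fast0, min=1e-6)
        p.add("k2", value=k_slow0, min=1e-6)
        def resid(p):
            F = (p["lam"] * np.exp(-p["k1"] * tau)
                 + (1 - p["lam"]) * np.exp(-p["k2"] * tau))
            return (p["N"] * F - H) / w
        out = lmfit.minimize(resid, p)
        fit = ExponentialFit(model="double", N=out.params["N"].value,
                             lam=out.params["lam"].value,
                             k1=out.params["k1"].value,
                             k2=out.params["k2"].value,
                             tau_min_fit=tau_min_fit, redchi=out.redchi,
                             success=out.success)
        fit.at_bound = fit.lam < 1e-6 or fit.lam > 1 - 1e-6
    pred = fit.N * fit.F(tau)
    ss_res = float(np.sum((H - pred) ** 2))
    ss_tot = float(np.sum((H - H.mean()) ** 2))
    fit.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not fit.success:
        warnings.warn("release-curve fit did not converge", stacklevel=2)
    return fit


def photobleach_regression(duty_ratios, k_loss):
    """OLS of k_loss against duty ratio: intercept = k_app, slope = k_pb.

    Requires >= 3 distinct duty ratios (the regression is otherwise
    unidentifiable).
    """
    dr = np.asarray(duty_ratios, dtype=float)
    kl = np.asarray(k_loss, dtype=float)
    if len(np.unique(dr)) < 3:
        raise ValueError("need >= 3 distinct duty ratios")
    res = sm.OLS(kl, sm.add_constant(dr)).fit()
    k_app, k_pb = res.params
    return float(k_app), float(k_pb), res


@dataclass
class RateEstimates:
    """Photobleach-corrected dissociation-rate estimates (s^-1)."""

    k_fast: float
    k_slow: float
    k_all: float
    k_pb: float
    dr: float
    clipped: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)


def correct_rates(fit: ExponentialFit, k_pb: float, dr: float = 1.0) -> RateEstimates:
    """Photobleach-corrected rates from a release-curve fit.

    k_fast/k_slow subtract k_pb*dr from the sorted fitted rates; k_all is
    the inverse mean lifetime of the fitted F, (int F) / (int tau F) - k_pb*dr.
    Negative corrected rates are clipped to zero and flagged.
    """
    kpb_eff = k_pb * dr
    kf_raw, ks_raw = fit.rates_sorted
    if fit.model == "single":
        k_all_raw = fit.k1
    else:
        lam, k1, k2 = fit.lam, fit.k1, fit.k2
        int_f = lam / k1 + (1 - lam) / k2
        int_tf = lam / k1**2 + (1 - lam) / k2**2
        k_all_raw = int_f / int_tf
    vals = {"k_fast": kf_raw - kpb_eff, "k_slow": ks_raw - kpb_eff,
            "k_all": k_all_raw - kpb_eff}
    clipped = [k for k, v in vals.items() if v < 0]
    if clipped:
        warnings.warn(f"photobleach correction clipped {clipped} at zero",
                      stacklevel=2)
    return RateEstimates(k_fast=max(vals["k_fast"], 0.0),
                         k_slow=max(vals["k_slow"], 0.0),
                         k_all=max(vals["k_all"], 0.0),
                         k_pb=k_pb, dr=dr, clipped=clipped)


def recruitment_ratio(fit_A: ExponentialFit, fit_P: ExponentialFit,
                      area_A: float, area_P: float,
                      duration_A: float = 1.0, duration_P: float = 1.0) -> float:
    """Anterior:posterior ratio of extrapolated per-area binding counts.

    N_{A/P} = F_{A/P}(0) / A_ROI; with equal acquisition durations this is
    the ratio of monomer recruitment rates k_on^A / k_on^P.
    """
    if area_A <= 0 or area_P <= 0:
        raise ValueError("ROI areas must be > 0")
    n_P = fit_P.N / area_P / duration_P
    if n_P == 0:
        raise ZeroDivisionError("zero posterior binding count")
    return (fit_A.N / area_A / duration_A) / n_P


def bootstrap_recruitment_ratio(life_A, life_P, area_A, area_P,
                                n_boot: int = 1000, seed: int = 0,
                                model: str = "double",
                                tau_min: float = 0.2,
                                tau_min_fit: float = 0.2,
                                ci_level: float = 0.95):
    """Bootstrap CI for the recruitment ratio by resampling pooled trajectories."""
    rng = np.random.default_rng(seed)
    life_A = np.asarray(life_A, float)
    life_P = np.asarray(life_P, float)

    def ratio(la, lp):
        fa = fit_release(build_release_curve(la, tau_min=tau_min), model=model,
                         tau_min_fit=tau_min_fit)
        fp = fit_release(build_release_curve(lp, tau_min=tau_min), model=model,
                         tau_min_fit=tau_min_fit)
        return recruitment_ratio(fa, fp, area_A, area_P)

    point = ratio(life_A, life_P)
    reps = []
    for _ in range(n_boot):
        la = rng.choice(life_A, size=len(life_A), replace=True)
        lp = rng.choice(life_P, size=len(life_P), replace=True)
        try:
            reps.append(ratio(la, lp))
        except Exception:
            continue
    lo, hi = np.quantile(reps, [(1 - ci_level) / 2, (1 + ci_level) / 2])
    return point, (float(lo), float(hi))


def size_dependent_koff(tracks: pd.DataFrame, horizon: float = 1.0,
                        min_count: int = 20) -> pd.DataFrame:
    """k_off(n) from per-size 1-s survival fractions, k_off(n) = -ln F_n.

    ``tracks`` needs columns size (initial-intensity size call) and lifetime.
    Sizes with fewer than ``min_count`` observations are masked; F_n = 0 is
    reported as a lower bound and flagged.
    """
    rows = []
    for n, grp in tracks.groupby("size"):
        cnt = len(grp)
        if cnt < min_count:
            rows.append({"n": n, "count": cnt, "F": np.nan, "k_off": np.nan,
                         "flag": "masked_low_count"})
            continue
        F = float((grp.lifetime > horizon).mean())
        if F == 0.0:
            rows.append({"n": n, "count": cnt, "F": 0.0,
                         "k_off": float(np.log(cnt + 1)) / horizon,
                         "flag": "lower_bound"})
        else:
            rows.append({"n": n, "count": cnt, "F": F,
                         "k_off": float(-np.log(F)) / horizon, "flag": ""})
    return pd.DataFrame(rows).sort_values("n").reset_index(drop=True)


# ---------------------------------------------------------------------------
# mobility
# ---------------------------------------------------------------------------

@dataclass
class MobilityDistribution:
    """Histogram of 100-ms displacements on the package-wide bin edges."""

    edges: np.ndarray
    density: np.ndarray          # probability mass per bin (sums to 1)
    source: str = "observed"

    def __post_init__(self):
        tot = self.density.sum()
        if tot > 0:
            self.density = self.density / tot


def _histogram(r: np.ndarray, source: str) -> MobilityDistribution:
    h, _ = np.histogram(r, bins=D100_BIN_EDGES)
    return MobilityDistribution(edges=D100_BIN_EDGES, density=h.astype(float),
                                source=source)


def d100_distribution(ts: TrajectorySet, roi: str | None = None,
                      interval: float = 0.1, min_lifetime: float = 0.2,
                      source: str = "observed") -> MobilityDistribution:
    """Displacements over ``interval`` for all segments of qualifying tracks."""
    lag = int(round(interval / ts.frame_interval))
    df = ts.samples
    if roi is not None:
        df = df[df.roi == roi]
    keep = ts.tracks[ts.tracks.lifetime >= min_lifetime].track_id
    df = df[df.track_id.isin(keep)].sort_values(["track_id", "frame"])
    g = df.groupby("track_id")
    dx = df.x_um - g.x_um.shift(lag)
    dy = df.y_um - g.y_um.shift(lag)
    r = np.hypot(dx, dy)
    return _histogram(r[np.isfinite(r)].to_numpy(), source)


def brownian_reference(D: float = 0.1, sigma_loc: float = 0.05,
                       n: int = 10000, seed: int = 0,
                       interval: float = 0.1) -> MobilityDistribution:
    """Reference D_100 for Brownian diffusion with Gaussian localization noise.

    Each displacement is a 2-D Gaussian with per-axis variance
    2 D * interval + 2 sigma_loc^2 (noise enters at both endpoints).
    """
    rng = np.random.default_rng(seed)
    var = 2.0 * D * interval + 2.0 * sigma_loc**2
    d = rng.normal(0.0, np.sqrt(var), size=(n, 2))
    return _histogram(np.hypot(d[:, 0], d[:, 1]), "brownian_reference")


def confined_reference(corral_radius: float = 0.06, D: float = 0.1,
                       sigma_loc: float = 0.05, n: int = 10000, seed: int = 0,
                       interval: float = 0.1) -> MobilityDistribution:
    """Reference D_100 for sub-diffusive (corral-confined) cortex-bound motion.

    Diffusion in a harmonic corral (OU process) with stationary per-axis SD
    ``corral_radius`` and relaxation rate 2 D / corral_radius^2.
    """
    rng = np.random.default_rng(seed)
    theta = 2.0 * D / corral_radius**2
    rho = np.exp(-theta * interval)
    # displacement of the stationary OU process: var = 2 sigma^2 (1 - rho)
    var = 2.0 * corral_radius**2 * (1.0 - rho) + 2.0 * sigma_loc**2
    d = rng.normal(0.0, np.sqrt(var), size=(n, 2))
    return _histogram(np.hypot(d[:, 0], d[:, 1]), "oligomer_reference")


def d100_mixture(observed: MobilityDistribution,
                 refs: dict[str, MobilityDistribution]) -> dict:
    """Non-negative mixture weights (summing to 1) of reference D_100 shapes.

    Constrained least squares via NNLS with an appended sum-to-one row.
    A degenerate design (near-identical references) is flagged rather than
    resolved arbitrarily.
    """
    names = list(refs)
    for name in names:
        if not np.array_equal(refs[name].edges, observed.edges):
            raise ValueError(f"bin-edge mismatch for reference {name!r}")
    M = np.column_stack([refs[n].density for n in names])
    flag = ""
    if len(names) >= 2:
        pair_dists = [np.abs(M[:, i] - M[:, j]).sum()
                      for i in range(len(names)) for j in range(i + 1, len(names))]
        if min(pair_dists) < 1e-3:
            flag = "degenerate_references"
    penalty = 1e3
    M_aug = np.vstack([M, penalty * np.ones(len(names))])
    b_aug = np.append(observed.density, penalty)
    w, _ = nnls(M_aug, b_aug)
    s = w.sum()
    if s > 0:
        w = w / s
    return {"weights": dict(zip(names, map(float, w))), "flag": flag}
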