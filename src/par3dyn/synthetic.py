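"""Synthetic single-molecule and spatial data with known ground truth.

Every generator is deterministic under a fixed seed and returns (or embeds)
the true parameter values used, so each inference stage has a round-trip
test: generate -> infer -> compare to truth.

What is emulated: Poisson binding in a flat ROI; exponential (or two-state
mixture) membrane dwell times competing with photobleaching at rate
k_pb * duty_ratio; Brownian or corral-confined 2-D motion sampled at the
frame interval with Gaussian localization noise; per-oligomer fluorescence
as n-fold scaled single-fluorophore Gaussians; FRAP recovery by
terminal-subunit exchange; and polarized initial membrane-density profiles
for the spatial model.  What is not: camera noise, detection/linking errors,
drift, and spatial gradients within an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import SizeDistribution, default_koff_table, steady_state_alpha
from .singlemol import TrajectorySet
from .spatial import FieldState, Grid1D

__all__ = [
    "GeneratorConfig",
    "simulate_trajectories",
    "simulate_duty_ratio_experiment",
    "simulate_intensity_sample",
    "simulate_frap",
    "frap_half_time",
    "make_initial_profile",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic acquisition; defaults mirror the measured
    study conditions (50-ms streaming exposure, k_pb = 1.04 /s, monomer
    k_off = 3.75 /s, D = 0.1 um^2/s, 50-nm localization SD, anterior:
    posterior recruitment 1.78:1)."""

    seed: int
    frame_interval: float = 0.05
    duration: float = 50.0
    duty_ratio: float = 1.0
    roi_areas: dict = field(default_factory=lambda: {"anterior": 100.0,
                                                     "posterior": 100.0})
    binding_rates: dict = field(default_factory=lambda: {"anterior": 1.78,
                                                         "posterior": 1.0})
    # dwell-time model: single rate (lam = 1) or two-state mixture
    lifetime_lam: float = 1.0
    lifetime_k1: float = 3.75
    lifetime_k2: float = 0.5
    k_pb: float = 1.04
    motion_model: str = "brownian"      # brownian | confined
    D: float = 0.1
    corral_radius: float = 0.06
    sigma_loc: float = 0.05
    mu_sm: float = 100.0
    sigma_sm: float = 30.0
    size_alpha: float = 0.73
    size_probs: np.ndarray | None = None
    n_max_size: int = 20
    k_off_by_size: np.ndarray = field(default_factory=lambda: default_koff_table(20))
    k_diss: float = 0.08

    def __post_init__(self):
        if not (0.0 < self.duty_ratio <= 1.0):
            raise ValueError("duty ratio must lie in (0, 1]")
        if self.lifetime_k1 < 0 or self.lifetime_k2 < 0 or self.k_pb < 0:
            raise ValueError("rates must be >= 0")

    def truth(self) -> dict:
        return {
            "binding_rates": dict(self.binding_rates),
            "lifetime": {"lam": self.lifetime_lam, "k1": self.lifetime_k1,
                         "k2": self.lifetime_k2},
            "k_pb": self.k_pb, "duty_ratio": self.duty_ratio,
            "D": self.D, "sigma_loc": self.sigma_loc,
            "mu_sm": self.mu_sm, "sigma_sm": self.sigma_sm,
            "size_alpha": self.size_alpha,
        }


def _sample_lifetimes(cfg: GeneratorConfig, n: int, rng) -> np.ndarray:
    k = np.where(rng.random(n) < cfg.lifetime_lam, cfg.lifetime_k1,
                 cfg.lifetime_k2)
    return rng.exponential(1.0 / k)


def _track_positions(cfg: GeneratorConfig, n_frames: int, side: float,
                     rng) -> np.ndarray:
    x0 = rng.uniform(0.0, side, size=2)
    dt = cfg.frame_interval
    if cfg.motion_model == "brownian":
        steps = rng.normal(0.0, np.sqrt(2 * cfg.D * dt), size=(n_frames - 1, 2))
        pos = x0 + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    elif cfg.motion_model == "confined":
        theta = 2.0 * cfg.D / cfg.corral_radius**2
        rho = np.exp(-theta * dt)
        sd_step = cfg.corral_radius * np.sqrt(1.0 - rho**2)
        pos = np.empty((n_frames, 2))
        dev = rng.normal(0.0, cfg.corral_radius, size=2)  # stationary start
        pos[0] = x0 + dev
        for i in range(1, n_frames):
            dev = rho * dev + rng.normal(0.0, sd_step, size=2)
            pos[i] = x0 + dev
    else:
        raise ValueError(f"unknown motion model {cfg.motion_model!r}")
    return pos + rng.normal(0.0, cfg.sigma_loc, size=pos.shape)


def simulate_trajectories(cfg: GeneratorConfig, sizes: np.ndarray | None = None,
                          roi_list=None, positions: bool = True) -> TrajectorySet:
    """Poisson binding, competing dwell/bleach clocks, frame-sampled motion.

    Observed dwell = min(kinetic lifetime, Exp(k_pb * duty_ratio) bleach
    time); tracks surviving to the movie end are flagged censored.  If
    ``sizes`` is given (one per eventual track, recycled across ROIs), each
    track's kinetic rate is replaced by k_off(size) and its intensity scaled
    n-fold -- used for size-resolved dissociation experiments.

    ``positions=False`` skips the frame-level table (lifetime-only studies
    run much faster; the per-track summary is unaffected).
    """
    rng = np.random.default_rng(cfg.seed)
    rois = roi_list if roi_list is not None else list(cfg.roi_areas)
    sample_rows = []
    track_rows = []
    tid = 0
    for roi in rois:
        area = cfg.roi_areas[roi]
        rate = cfg.binding_rates[roi]
        n_tracks = rng.poisson(rate * area * cfg.duration)
        t0 = rng.uniform(0.0, cfg.duration, n_tracks)
        if sizes is None:
            size_arr = np.ones(n_tracks, dtype=int)
            kin = _sample_lifetimes(cfg, n_tracks, rng)
        else:
            size_arr = np.asarray(sizes, dtype=int)[
                rng.integers(0, len(sizes), n_tracks)]
            koff = np.asarray(cfg.k_off_by_size, dtype=float)[size_arr - 1]
            kin = np.where(koff > 0, rng.exponential(1.0 / np.clip(koff, 1e-12, None)),
                           np.inf)
        bleach = rng.exponential(1.0 / (cfg.k_pb * cfg.duty_ratio), n_tracks) \
            if cfg.k_pb > 0 else np.full(n_tracks, np.inf)
        dwell = np.minimum(kin, bleach)
        censored = t0 + dwell > cfg.duration
        dwell = np.minimum(dwell, cfg.duration - t0)
        n_frames = np.maximum(np.ceil(dwell / cfg.frame_interval), 1).astype(int)
        side = np.sqrt(area)
        for i in range(n_tracks):
            nf = n_frames[i]
            if positions:
                pos = _track_positions(cfg, nf, side, rng)
                f0 = int(t0[i] / cfg.frame_interval)
                frames = f0 + np.arange(nf)
                inten = rng.normal(size_arr[i] * cfg.mu_sm,
                                   np.sqrt(size_arr[i]) * cfg.sigma_sm, nf)
                sample_rows.append(pd.DataFrame({
                    "track_id": tid, "roi": roi, "frame": frames,
                    "t_s": frames * cfg.frame_interval,
                    "x_um": pos[:, 0], "y_um": pos[:, 1],
                    "intensity_au": inten,
                }))
            track_rows.append((tid, roi, nf * cfg.frame_interval,
                               bool(censored[i]), int(size_arr[i])))
            tid += 1
    samples = (pd.concat(sample_rows, ignore_index=True) if sample_rows
               else pd.DataFrame(columns=["track_id", "roi", "frame", "t_s",
                                          "x_um", "y_um", "intensity_au"]))
    tracks = pd.DataFrame(track_rows, columns=["track_id", "roi", "lifetime",
                                               "censored", "size"])
    return TrajectorySet(samples=samples, tracks=tracks,
                         frame_interval=cfg.frame_interval,
                         roi_areas=dict(cfg.roi_areas), duration=cfg.duration,
                         truth=cfg.truth())


def simulate_duty_ratio_experiment(cfg: GeneratorConfig,
                                   dr_list=(0.05, 0.1, 0.2, 1.0)) -> dict:
    """Shared kinetics, varying only the effective bleach rate k_pb * dr."""
    out = {}
    for i, dr in enumerate(dr_list):
        out[dr] = simulate_trajectories(
            replace(cfg, duty_ratio=dr, seed=cfg.seed + 1000 * i))
    return out


def simulate_intensity_sample(cfg: GeneratorConfig, n_features: int):
    """Sizes from the configured distribution; intensities N(n mu, n sigma^2).

    Returns (intensities, true_sizes); negative draws are redrawn (the
    intensity model is truncated at zero).
    """
    rng = np.random.default_rng(cfg.seed)
    n = np.arange(1, cfg.n_max_size + 1)
    if cfg.size_probs is not None:
        p = np.asarray(cfg.size_probs, dtype=float)
        p = p / p.sum()
    else:
        p = cfg.size_alpha ** (n - 1)
        p = p / p.sum()
    sizes = rng.choice(n, size=n_features, p=p)
    inten = rng.normal(sizes * cfg.mu_sm, np.sqrt(sizes) * cfg.sigma_sm)
    bad = inten <= 0
    while bad.any():
        inten[bad] = rng.normal(sizes[bad] * cfg.mu_sm,
                                np.sqrt(sizes[bad]) * cfg.sigma_sm)
        bad = inten <= 0
    return inten, sizes


def simulate_frap(cfg: GeneratorConfig, dist: SizeDistribution,
                  t_grid: np.ndarray, n_oligomers: int = 5000):
    """Stochastic full-field bleach recovery by terminal-subunit exchange.

    Each sampled n-mer recovers its min(n, 2) terminal slots independently
    at rate k_diss; monomers (n = 1) turn over at k_off(1); interior
    subunits do not exchange on the simulated timescale.  Returns the
    recovery fraction R(t) on t_grid (R -> terminal fraction as t -> inf).
    """
    rng = np.random.default_rng(cfg.seed)
    t_grid = np.asarray(t_grid, dtype=float)
    p = dist.A / dist.A.sum()
    ns = rng.choice(dist.n, size=n_oligomers, p=p)
    total_subunits = ns.sum()
    rec = np.zeros_like(t_grid)
    is_mono = ns == 1
    n_mono = int(is_mono.sum())
    if n_mono:
        t_mono = rng.exponential(1.0 / cfg.k_off_by_size[0], n_mono)
        rec += (t_mono[:, None] <= t_grid[None, :]).sum(axis=0)
    n_term = np.minimum(ns[~is_mono], 2).sum()
    if n_term:
        t_term = rng.exponential(1.0 / cfg.k_diss, int(n_term))
        rec += (t_term[:, None] <= t_grid[None, :]).sum(axis=0)
    return rec / total_subunits


def frap_half_time(t_grid, recovery) -> float:
    """Time at which recovery reaches half of its final plateau."""
    plateau = recovery[-1]
    return float(np.interp(0.5 * plateau, recovery, t_grid))


def make_initial_profile(template: str, grid: Grid1D, K_P: float,
                         n_max: int = 50, amplitude: float = 0.25,
                         ratio: float = 8.0, width: float = 1.25,
                         total: float = 1.0,
                         composition: str = "geometric",
                         koff_hat: np.ndarray | None = None) -> FieldState:
    """Membrane-density profile mimicking the start of maintenance phase.

    ``polarized``: logistic step (scale ``width`` um, i.e. a ~4.4*width
    10-90% transition) from an anterior plateau ``amplitude`` down to
    ``amplitude / ratio`` posteriorly; ``uniform``: flat at ``amplitude``.
    The per-size composition at each point is the local geometric
    distribution implied by x = K_P * A_tot(x), rescaled so the subunit
    total is exact despite truncation; with ``composition="steady"`` (and a
    dimensionless ``koff_hat`` table) it is instead the exact local steady
    distribution of the truncated size-structured system, which differs
    from geometric when oligomer detachment is not slow.  The cytoplasmic
    pool carries the remainder of ``total``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    x = grid.x
    if template == "uniform":
        a_tot = np.full(grid.n_cells, amplitude)
    elif template == "polarized":
        a_post = amplitude / ratio
        a_tot = a_post + (amplitude - a_post) / (
            1.0 + np.exp((x - grid.length / 2.0) / width))
    else:
        raise ValueError(f"unknown template {template!r}")
    n = np.arange(1, n_max + 1)[:, None]
    if composition == "geometric":
        alpha = np.array([steady_state_alpha(K_P * a) for a in a_tot])
        A1 = a_tot * (1.0 - alpha) ** 2
        A = A1[None, :] * alpha[None, :] ** (n - 1)
        subunits = (n * A).sum(axis=0)
        scale = np.divide(a_tot, subunits, out=np.zeros_like(a_tot),
                          where=subunits > 0)
        A = A * scale[None, :]
    elif composition == "steady":
        from .kinetics import RateParameters, becker_doring_profile, solve_a1_for_total
        if koff_hat is None:
            koff_hat = default_koff_table(n_max) / 0.08
        params = RateParameters(k_on=0.0, k_off_by_size=np.asarray(koff_hat),
                                k_ass=K_P, k_diss=1.0, n_max=n_max)
        A = np.empty((n_max, grid.n_cells))
        for j, a in enumerate(a_tot):
            A[:, j] = becker_doring_profile(solve_a1_for_total(params, a),
                                            params).A
    else:
        raise ValueError(f"unknown composition {composition!r}")
    C = total - a_tot.mean()
    if C < 0:
        raise ValueError("membrane mass exceeds the configured total")
    return FieldState(grid=grid, A=A, C=float(C), t=0.0)
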