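"""Oligomer stoichiometry inference from calibrated fluorescence intensities.

A single fluorophore contributes a Gaussian intensity N(mu_sm, sigma_sm^2);
an n-mer contributes N(n mu_sm, n sigma_sm^2).  Three estimators of the
size distribution over n = 1..20 are provided: interval binning, an
empirical-Bayes (EM) posterior update, and constrained maximum-likelihood
decomposition of the intensity histogram.  Geometric fits of the resulting
distributions yield the oligomerization strength alpha and mean size s, and
paired (density, size) measurements yield the self-affinity K_P through
s = 2 A K_P / (sqrt(1 + 4 A K_P) - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls
from scipy.stats import norm

__all__ = [
    "SingleMoleculeCalibration",
    "SizeDistributionEstimate",
    "calibrate_single_molecule",
    "infer_sizes_binning",
    "infer_sizes_bayesian",
    "infer_sizes_mle",
    "fit_geometric",
    "fit_density_size_relation",
]

N_MAX_SIZING = 20


@dataclass(frozen=True)
class SingleMoleculeCalibration:
    """Mean and SD of the single-fluorophore intensity (a.u.)."""

    mu_sm: float
    sigma_sm: float
    n_samples: int = 0
    n_outliers: int = 0
    bimodal_warning: bool = False

    def __post_init__(self):
        if self.mu_sm <= 0 or self.sigma_sm <= 0:
            raise ValueError("calibration requires mu_sm > 0 and sigma_sm > 0 "
                             "(degenerate sample rejected)")


def calibrate_single_molecule(intensities,
                              min_samples: int = 200) -> SingleMoleculeCalibration:
    """Gaussian fit to post-bleach intensities; 4-sigma outliers dropped once.

    A bimodality heuristic (2- vs 1-component Gaussian mixture BIC) issues a
    warning when the post-bleach sample looks contaminated by unbleached
    oligomers.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < min_samples:
        raise ValueError(f"need >= {min_samples} intensity samples, got {len(x)}")
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("constant intensities: sigma_sm = 0 is degenerate")
    keep = np.abs(x - mu) <= 4.0 * sd
    n_out = int((~keep).sum())
    if n_out:
        mu, sd = float(x[keep].mean()), float(x[keep].std(ddof=1))
    bimodal = False
    try:
        from sklearn.mixture import GaussianMixture
        xr = x[keep].reshape(-1, 1)
        b1 = GaussianMixture(1, random_state=0).fit(xr).bic(xr)
        b2 = GaussianMixture(2, random_state=0).fit(xr).bic(xr)
        if b2 < b1 - 10.0:
            bimodal = True
            warnings.warn("post-bleach intensity sample looks bimodal; "
                          "calibration may be contaminated", stacklevel=2)
    except Exception:
        pass
    return SingleMoleculeCalibration(mu_sm=mu, sigma_sm=sd, n_samples=len(x),
                                     n_outliers=n_out, bimodal_warning=bimodal)


@dataclass
class SizeDistributionEstimate:
    """Estimated probabilities over oligomer sizes 1..n_max."""

    probabilities: np.ndarray
    method: str
    n_features: int = 0
    n_discarded: int = 0
    converged: bool = True
    counts: np.ndarray | None = None

    @property
    def n(self) -> np.ndarray:
        return np.arange(1, len(self.probabilities) + 1)

    @property
    def s(self) -> float:
        """Mean oligomer size computed directly from the estimate."""
        return float(np.dot(self.n, self.probabilities))


def infer_sizes_binning(intensities, calib: SingleMoleculeCalibration,
                        n_max: int = N_MAX_SIZING) -> SizeDistributionEstimate:
    """Interval binning: I in [(n-0.5) mu_sm, (n+0.5) mu_sm) -> size n.

    Intensities below 0.5 mu_sm are discarded (and counted); intensities
    beyond the top interval are assigned to n_max.
    """
    x = np.asarray(intensities, dtype=float)
    n_call = np.floor(x / calib.mu_sm + 0.5).astype(int)
    keep = n_call >= 1
    n_call = np.minimum(n_call[keep], n_max)
    counts = np.bincount(n_call, minlength=n_max + 1)[1:].astype(float)
    tot = counts.sum()
    probs = counts / tot if tot > 0 else counts
    return SizeDistributionEstimate(probabilities=probs, method="binning",
                                    n_features=int(tot),
                                    n_discarded=int((~keep).sum()),
                                    counts=counts)


def _nmer_loglik(x: np.ndarray, calib: SingleMoleculeCalibration,
                 n_max: int) -> np.ndarray:
    """log N(x; n mu, n sigma^2) for each feature (rows) and size (cols)."""
    n = np.arange(1, n_max + 1)
    mu = n * calib.mu_sm
    sd = np.sqrt(n) * calib.sigma_sm
    return norm.logpdf(x[:, None], loc=mu[None, :], scale=sd[None, :])


def infer_sizes_bayesian(intensities, calib: SingleMoleculeCalibration,
                         n_max: int = N_MAX_SIZING, tol: float = 1e-6,
                         max_iter: int = 500) -> SizeDistributionEstimate:
    """Empirical-Bayes (EM) size inference.

    Starting from a uniform prior over 1..n_max, per-feature posteriors are
    computed under the n-mer Gaussian intensity model and the population
    prior is replaced by the mean posterior, iterating to an L1 fixed point.
    """
    x = np.asarray(intensities, dtype=float)
    loglik = _nmer_loglik(x, calib, n_max)
    prior = np.full(n_max, 1.0 / n_max)
    converged = False
    for _ in range(max_iter):
        logpost = loglik + np.log(np.clip(prior, 1e-300, None))[None, :]
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        new = post.mean(axis=0)
        if np.abs(new - prior).sum() < tol:
            prior = new
            converged = True
            break
        prior = new
    if not converged:
        warnings.warn("Bayesian size inference did not converge; returning "
                      "last iterate", stacklevel=2)
    return SizeDistributionEstimate(probabilities=prior, method="bayesian",
                                    n_features=len(x), converged=converged)


def infer_sizes_mle(intensities, calib: SingleMoleculeCalibration,
                    n_max: int = N_MAX_SIZING,
                    bin_width: float | None = None) -> SizeDistributionEstimate:
    """Maximum-likelihood weights of the n-mer Gaussian mixture.

    The intensity histogram is decomposed as a non-negative weighted sum of
    the 1..n_max n-mer intensity distributions (constrained least squares on
    binned probabilities); rank deficiency at large sigma_sm is flagged.
    """
    x = np.asarray(intensities, dtype=float)
    bw = bin_width if bin_width is not None else calib.sigma_sm / 2.0
    edges = np.arange(0.0, (n_max + 2) * calib.mu_sm + bw, bw)
    hist, _ = np.histogram(x, bins=edges)
    target = hist / hist.sum()
    n = np.arange(1, n_max + 1)
    mu = n * calib.mu_sm
    sd = np.sqrt(n) * calib.sigma_sm
    cdf = norm.cdf(edges[:, None], loc=mu[None, :], scale=sd[None, :])
    M = np.diff(cdf, axis=0)
    if np.linalg.cond(M.T @ M) > 1e12:
        warnings.warn("n-mer design matrix is rank deficient (sigma_sm too "
                      "large); weights may be unstable", stacklevel=2)
    w, _ = nnls(M, target)
    s = w.sum()
    probs = w / s if s > 0 else w
    return SizeDistributionEstimate(probabilities=probs, method="mle",
                                    n_features=len(x))


def fit_geometric(estimate: SizeDistributionEstimate) -> tuple[float, float, float]:
    """Weighted log-linear fit of A_n = A_1 alpha^(n-1) to an estimate.

    Returns (A_1, alpha, s) where s is computed directly from the estimate
    (sum n p_n), not from 1/(1 - alpha) -- the two are reported separately
    because empirical histograms need not be exactly geometric.
    """
    p = estimate.probabilities
    occ = p > 0
    if occ.sum() < 2:
        raise ValueError("alpha undefined with a single occupied size class")
    if occ.sum() < 3:
        warnings.warn("fewer than 3 occupied size classes; geometric fit is "
                      "poorly constrained", stacklevel=2)
    n = estimate.n[occ]
    w = p[occ]
    slope, intercept = np.polyfit(n - 1, np.log(p[occ]), 1, w=np.sqrt(w))
    alpha = float(np.clip(np.exp(slope), 0.0, 1.0 - 1e-12))
    A_1 = float(np.exp(intercept))
    return A_1, alpha, estimate.s


def fit_density_size_relation(A_tot, s, p0: float | None = None) -> float:
    """One-parameter fit of the density-size relation for the self-affinity K_P.

    s = 2 A K_P / (sqrt(1 + 4 A K_P) - 1); requires >= 4 density levels
    spanning a >= 4-fold range.
    """
    A = np.asarray(A_tot, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(A) < 4:
        raise ValueError("need >= 4 density levels")
    if A.max() < 4.0 * A.min():
        warnings.warn("density range below 4-fold; K_P weakly identified",
                      stacklevel=2)
    if np.allclose(A, A[0]):
        raise ValueError("all densities equal: K_P unidentifiable")

    def model(A, K):
        x = np.clip(A * K, 1e-12, None)
        return 2.0 * x / (np.sqrt(1.0 + 4.0 * x) - 1.0)

    if p0 is None:
        # invert the median point: alpha = 1 - 1/s, x = alpha/(1-alpha)^2
        a_med = np.clip(1.0 - 1.0 / np.median(s), 1e-6, 1 - 1e-6)
        p0 = float(a_med / (1 - a_med) ** 2 / np.median(A))
    if np.all(s <= 1.0 + 1e-12):
        return 0.0
    popt, _ = curve_fit(model, A, s, p0=[max(p0, 1e-9)],
                        bounds=(0.0, np.inf), maxfev=10000)
    return float(popt[0])
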