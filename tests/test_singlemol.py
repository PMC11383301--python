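"""Dwell-time, photobleaching and mobility estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from par3dyn.singlemol import (
    D100_BIN_EDGES,
    ExponentialFit,
    MobilityDistribution,
    ReleaseCurve,
    brownian_reference,
    build_release_curve,
    confined_reference,
    correct_rates,
    d100_mixture,
    fit_release,
    photobleach_regression,
    recruitment_ratio,
    size_dependent_koff,
)


def noiseless_curve(N, lam, k1, k2, frame=0.05, n_points=120):
    tau = frame * np.arange(1, n_points + 1)
    H = N * (lam * np.exp(-k1 * tau) + (1 - lam) * np.exp(-k2 * tau))
    return ReleaseCurve(tau=tau, H=H)


class TestReleaseCurve:
    def test_counting_example(self):
        c = build_release_curve([0.1, 0.3, 0.3, 1.0], tau_min=0.2)
        assert c.H[np.searchsorted(c.tau, 0.2)] == 3
        assert c.H[np.searchsorted(c.tau, 0.5)] == 1
        assert c.n_excluded_short == 1

    def test_all_short_is_empty(self):
        c = build_release_curve([0.05, 0.1], tau_min=0.2)
        assert c.empty

    def test_survival_of_exponential_is_loglinear(self, rng):
        k = 1.3
        life = rng.exponential(1.0 / k, 5000)
        c = build_release_curve(life, tau_min=0.0)
        good = c.H > 20
        slope, icpt = np.polyfit(c.tau[good], np.log(c.H[good]), 1)
        resid = np.log(c.H[good]) - (slope * c.tau[good] + icpt)
        r2 = 1 - resid.var() / np.log(c.H[good]).var()
        assert r2 > 0.99
        assert -slope == pytest.approx(k, rel=0.05)

    @given(st.lists(st.floats(min_value=0.01, max_value=5.0), min_size=1,
                    max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_counts_match_brute_force(self, lifetimes):
        c = build_release_curve(lifetimes, tau_min=0.2)
        kept = [x for x in lifetimes if x >= 0.2]
        if not kept:
            assert c.empty
            return
        for tau, h in zip(c.tau, c.H):
            assert h == sum(1 for x in kept if x > tau)
        assert np.all(np.diff(c.H) <= 0)


class TestFitRelease:
    def test_noiseless_single(self):
        c = noiseless_curve(3000, 1.0, 1.12, 1.12)
        f = fit_release(c, model="single", tau_min_fit=0.2)
        assert f.k1 == pytest.approx(1.12, rel=1e-6)
        assert f.N == pytest.approx(3000, rel=1e-6)

    def test_noiseless_double(self):
        c = noiseless_curve(5000, 0.6, 4.0, 0.5, n_points=200)
        f = fit_release(c, model="double", tau_min_fit=0.2)
        kf, ks = f.rates_sorted
        assert kf == pytest.approx(4.0, rel=1e-4)
        assert ks == pytest.approx(0.5, rel=1e-4)
        lam_fast = f.lam if f.k1 >= f.k2 else 1 - f.lam
        assert lam_fast == pytest.approx(0.6, rel=1e-4)

    def test_label_swap_invariance(self):
        # swapping (lam, k1) <-> (1-lam, k2) gives the identical curve and
        # identical sorted rates
        a = noiseless_curve(5000, 0.6, 4.0, 0.5, n_points=200)
        b = noiseless_curve(5000, 0.4, 0.5, 4.0, n_points=200)
        fa = fit_release(a, model="double")
        fb = fit_release(b, model="double")
        assert fa.rates_sorted == pytest.approx(fb.rates_sorted, rel=1e-6)

    def test_too_few_points(self):
        c = noiseless_curve(10, 1.0, 1.0, 1.0, n_points=5)
        with pytest.raises(ValueError):
            fit_release(c, model="double", tau_min_fit=0.2)


class TestPhotobleachRegression:
    def test_exact_recovery(self):
        dr = np.array([0.05, 0.1, 0.2, 1.0])
        k_loss = 0.08 + 1.04 * dr
        k_app, k_pb, _ = photobleach_regression(dr, k_loss)
        assert k_app == pytest.approx(0.08, abs=1e-12)
        assert k_pb == pytest.approx(1.04, abs=1e-12)

    def test_identical_duty_ratios_refused(self):
        with pytest.raises(ValueError):
            photobleach_regression([0.1, 0.1, 0.1], [1.0, 1.1, 1.2])


class TestCorrectRates:
    def test_single_exponential_identity(self):
        f = ExponentialFit(model="single", N=100, lam=1.0, k1=2.0, k2=None,
                           tau_min_fit=0.2)
        r = correct_rates(f, k_pb=0.5)
        assert r.k_all == pytest.approx(2.0 - 0.5)

    def test_double_exponential_integral(self):
        # (0.5/4 + 0.5/1) / (0.5/16 + 0.5/1) = 0.625 / 0.53125
        f = ExponentialFit(model="double", N=100, lam=0.5, k1=4.0, k2=1.0,
                           tau_min_fit=0.2)
        r = correct_rates(f, k_pb=0.0)
        assert r.k_all == pytest.approx(0.625 / 0.53125, rel=1e-12)
        assert r.k_fast == 4.0
        assert r.k_slow == 1.0

    def test_overcorrection_clipped_and_flagged(self):
        f = ExponentialFit(model="single", N=10, lam=1.0, k1=0.3, k2=None,
                           tau_min_fit=0.2)
        with pytest.warns(UserWarning):
            r = correct_rates(f, k_pb=1.0)
        assert r.k_all == 0.0
        assert "k_all" in r.clipped

    def test_duty_ratio_scales_correction(self):
        f = ExponentialFit(model="single", N=10, lam=1.0, k1=1.0, k2=None,
                           tau_min_fit=0.2)
        r = correct_rates(f, k_pb=1.0, dr=0.1)
        assert r.k_all == pytest.approx(0.9)


class TestRecruitmentRatio:
    def make_fit(self, N):
        return ExponentialFit(model="single", N=N, lam=1.0, k1=1.0, k2=None,
                              tau_min_fit=0.2)

    def test_identical_sides(self):
        assert recruitment_ratio(self.make_fit(500), self.make_fit(500),
                                 100.0, 100.0) == 1.0

    def test_area_scaling(self):
        r1 = recruitment_ratio(self.make_fit(500), self.make_fit(500),
                               100.0, 100.0)
        r2 = recruitment_ratio(self.make_fit(500), self.make_fit(500),
                               50.0, 100.0)
        assert r2 == pytest.approx(2 * r1)

    def test_zero_posterior(self):
        with pytest.raises(ZeroDivisionError):
            recruitment_ratio(self.make_fit(500), self.make_fit(0),
                              100.0, 100.0)


class TestSizeDependentKoff:
    def test_full_survival_gives_zero_rate(self):
        tracks = pd.DataFrame({"size": [1] * 50, "lifetime": [2.0] * 50})
        out = size_dependent_koff(tracks)
        assert out.k_off.iloc[0] == 0.0
        assert out.F.iloc[0] == 1.0

    def test_survival_fraction_maps_to_rate(self):
        n_tracks = 10000
        rng = np.random.default_rng(0)
        life = rng.exponential(1 / 2.7, n_tracks)
        tracks = pd.DataFrame({"size": 1, "lifetime": life})
        out = size_dependent_koff(tracks)
        # binomial CI on F = e^-2.7
        F = np.exp(-2.7)
        se = np.sqrt(F * (1 - F) / n_tracks)
        assert abs(np.exp(-out.k_off.iloc[0]) - F) < 3 * se

    def test_low_counts_masked(self):
        tracks = pd.DataFrame({"size": [3] * 5, "lifetime": [2.0] * 5})
        out = size_dependent_koff(tracks)
        assert out.flag.iloc[0] == "masked_low_count"
        assert np.isnan(out.k_off.iloc[0])

    def test_generator_table_recovery(self):
        from par3dyn.synthetic import GeneratorConfig, simulate_trajectories
        cfg = GeneratorConfig(seed=21, k_pb=0.0, duration=200.0,
                              binding_rates={"anterior": 0.15,
                                             "posterior": 0.0})
        sizes = np.repeat([1, 2, 3], 400)
        ts = simulate_trajectories(cfg, sizes=sizes, roi_list=["anterior"],
                                   positions=False)
        out = size_dependent_koff(ts.tracks[~ts.tracks.censored])
        truth = {1: 2.7, 2: 0.8, 3: 0.2}
        for n, k in truth.items():
            row = out[out.n == n].iloc[0]
            F, cnt = np.exp(-k), row["count"]
            se = np.sqrt(F * (1 - F) / cnt)
            assert abs(row.F - F) < 3.5 * se


class TestMobility:
    def test_brownian_rms(self):
        # noiseless: RMS 100-ms displacement = sqrt(4 D t) = 0.2 um
        rng = np.random.default_rng(0)
        d = rng.normal(0, np.sqrt(2 * 0.1 * 0.1), size=(20000, 2))
        rms = np.sqrt((d**2).sum(axis=1).mean())
        assert rms == pytest.approx(0.2, rel=0.02)
        ref = brownian_reference(D=0.1, sigma_loc=0.0, n=20000, seed=1)
        mids = 0.5 * (ref.edges[:-1] + ref.edges[1:])
        rms_hist = np.sqrt((ref.density * mids**2).sum())
        assert rms_hist == pytest.approx(0.2, rel=0.05)

    def test_zero_diffusion_is_localization_noise(self):
        # D = 0: displacement is Rayleigh with scale sqrt(2) sigma_loc
        ref = brownian_reference(D=0.0, sigma_loc=0.05, n=50000, seed=2)
        mids = 0.5 * (ref.edges[:-1] + ref.edges[1:])
        mean_r = (ref.density * mids).sum()
        expected = np.sqrt(2) * 0.05 * np.sqrt(np.pi / 2)
        assert mean_r == pytest.approx(expected, rel=0.05)

    def test_determinism(self):
        a = brownian_reference(seed=3)
        b = brownian_reference(seed=3)
        np.testing.assert_array_equal(a.density, b.density)

    def test_mixture_identifies_pure_reference(self):
        refs = {"oligomer": confined_reference(seed=4),
                "brownian": brownian_reference(seed=5)}
        obs = brownian_reference(seed=5)
        w = d100_mixture(obs, refs)["weights"]
        assert w["brownian"] == pytest.approx(1.0, abs=1e-6)
        assert w["oligomer"] == pytest.approx(0.0, abs=1e-6)

    def test_blend_recovery(self):
        refs = {"oligomer": confined_reference(seed=6),
                "brownian": brownian_reference(seed=7)}
        blend = 0.25 * refs["oligomer"].density + 0.75 * refs["brownian"].density
        obs = MobilityDistribution(D100_BIN_EDGES, blend)
        w = d100_mixture(obs, refs)["weights"]
        assert w["oligomer"] == pytest.approx(0.25, abs=0.02)
        assert w["brownian"] == pytest.approx(0.75, abs=0.02)

    def test_identical_references_flagged(self):
        r = brownian_reference(seed=8)
        refs = {"a": r, "b": MobilityDistribution(r.edges, r.density.copy())}
        out = d100_mixture(r, refs)
        assert out["flag"] == "degenerate_references"

    def test_bin_mismatch_raises(self):
        r = brownian_reference(seed=9)
        bad = MobilityDistribution(r.edges[:-1], r.density[:-1])
        with pytest.raises(ValueError):
            d100_mixture(r, {"a": bad})
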