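"""Feedback model: calibration, LPA classification, PDE simulations."""

import json

import numpy as np
import pytest

from par3dyn.kinetics import KineticsError
from par3dyn.spatial import (
    PERTURBATION_SCENARIOS,
    FeedbackParameters,
    Grid1D,
    calibrate,
    depletion_response,
    local_steady_states,
    lpa_classify,
    perturbation_scenarios,
    phase_diagram,
    recruitment_rate,
    simulate_maintenance,
    uniform_membrane_fraction,
)
from par3dyn.synthetic import make_initial_profile


class TestRecruitmentRate:
    def test_basal_at_zero_density(self, embryo_fb):
        assert recruitment_rate(0.0, embryo_fb) == pytest.approx(embryo_fb.K_on)

    def test_saturation(self, embryo_fb):
        k_sat = embryo_fb.K_on * (1 + embryo_fb.K_f * embryo_fb.A_sat)
        assert recruitment_rate(embryo_fb.A_sat, embryo_fb) == pytest.approx(k_sat)
        assert recruitment_rate(10 * embryo_fb.A_sat, embryo_fb) == \
            pytest.approx(k_sat)

    def test_fixed_bias_flat_profile(self, embryo_fb):
        fb = embryo_fb.replace(bias_mode="fixed_bias",
                               bias_profile=np.ones(4))
        out = recruitment_rate(np.array([0.0, 0.05, 0.2, 1.0]), fb)
        np.testing.assert_allclose(out, fb.K_on)


class TestCalibration:
    def test_membrane_fraction_constraint(self, embryo_fb):
        assert uniform_membrane_fraction(embryo_fb) == pytest.approx(0.10,
                                                                     abs=1e-6)

    def test_no_feedback_reduces_to_constant_kon(self):
        fb = calibrate(FeedbackParameters(K_f=0.0, K_P=10.0))
        A = np.array([0.0, 0.05, 0.5])
        np.testing.assert_allclose(recruitment_rate(A, fb), fb.K_on)

    def test_total_scaling_consistency(self):
        # with fixed dimensionless parameters, rescaling the conserved total
        # leaves the normalized solution invariant
        fb1 = calibrate(FeedbackParameters(K_f=5.0, K_P=30.0), total=1.0)
        fb2 = calibrate(FeedbackParameters(K_f=5.0, K_P=30.0), total=2.0)
        assert uniform_membrane_fraction(fb2, total=2.0) == pytest.approx(
            uniform_membrane_fraction(fb1, total=1.0), abs=1e-8)

    def test_infeasible_fraction(self):
        with pytest.raises(Exception):
            calibrate(FeedbackParameters(K_f=1.0, K_P=1.0),
                      target_membrane_fraction=1.5)


class TestLPA:
    def test_no_recruitment_feedback_cannot_polarize(self):
        for kp in [10.0, 62.0, 150.0]:
            fb = calibrate(FeedbackParameters(K_f=0.0, K_P=kp))
            assert lpa_classify(fb).label == "no_polarity"

    def test_no_oligomerization_cannot_polarize(self):
        for kf in [5.0, 14.5, 40.0]:
            fb = calibrate(FeedbackParameters(K_f=kf, K_P=0.0))
            assert lpa_classify(fb).label == "no_polarity"

    def test_embryo_point_is_inducible(self, embryo_fb):
        reg = lpa_classify(embryo_fb)
        assert reg.label == "inducible_polarity"
        assert reg.n_stable >= 2
        assert reg.transition_ok

    def test_classification_insensitive_to_patch_depth(self, embryo_fb):
        for level in [0.02, 0.05, 0.10, 0.20]:
            assert lpa_classify(embryo_fb, depletion_level=level).label == \
                "inducible_polarity"

    def test_uniform_state_always_present(self, embryo_fb):
        states = local_steady_states(embryo_fb)
        assert any(abs(s.A_tot - 0.10) < 1e-6 for s in states)


@pytest.fixture(scope="module")
def small_diagram():
    return phase_diagram(np.array([0.0, 5.0, 10.0, 20.0]),
                         np.array([0.0, 20.0, 62.0, 120.0]))


class TestPhaseDiagram:
    def test_no_feedback_row_uniform(self, small_diagram):
        assert all(lbl == "no_polarity" for lbl in small_diagram.labels[0, :])
        assert all(lbl == "no_polarity" for lbl in small_diagram.labels[:, 0])

    def test_synergy_monotone_boundary(self, small_diagram):
        # if a cell is inducible, every cell up-right of it is inducible
        lab = small_diagram.labels
        ind = lab == "inducible_polarity"
        for i in range(ind.shape[0]):
            for j in range(ind.shape[1]):
                if ind[i, j]:
                    assert ind[i:, j:].all()

    def test_refinement_consistency(self, small_diagram):
        sub = phase_diagram(np.array([5.0, 20.0]), np.array([20.0, 120.0]))
        for i, kf in enumerate(sub.K_f_grid):
            for j, kp in enumerate(sub.K_P_grid):
                i0 = list(small_diagram.K_f_grid).index(kf)
                j0 = list(small_diagram.K_P_grid).index(kp)
                assert sub.labels[i, j] == small_diagram.labels[i0, j0]

    def test_grid_must_be_monotone(self):
        with pytest.raises(KineticsError):
            phase_diagram(np.array([1.0, 1.0]), np.array([0.0, 1.0]))


class TestMaintenanceSimulation:
    def test_uniform_init_stays_uniform(self, embryo_fb, grid):
        init = make_initial_profile("uniform", grid, K_P=embryo_fb.K_P,
                                    amplitude=0.10, ratio=1.0)
        res = simulate_maintenance(init, embryo_fb, t_sim=120.0)
        assert res.asymmetry == pytest.approx(1.0, abs=1e-6)

    def test_mass_conservation(self, control_run, polarized_init):
        assert control_run.final.total == pytest.approx(polarized_init.total,
                                                        rel=1e-6)

    def test_polarized_init_maintains_asymmetry(self, control_run):
        assert control_run.asymmetry > 5.0
        assert control_run.recruitment_ratio > 1.5

    def test_uniform_state_matches_well_mixed(self, embryo_fb, grid):
        # the spatial uniform steady state carries the calibrated membrane
        # fraction of the pool, matching the well-mixed solution; the init
        # must carry the exact steady composition (with non-negligible
        # oligomer detachment the geometric composition over-fluxes and can
        # tip the state into the low basin)
        init = make_initial_profile("uniform", grid, K_P=embryo_fb.K_P,
                                    amplitude=0.10, ratio=1.0,
                                    composition="steady",
                                    koff_hat=embryo_fb.koff_hat)
        res = simulate_maintenance(init, embryo_fb, t_sim=600.0)
        assert res.final.A_tot.mean() == pytest.approx(0.10, rel=1e-5)

    def test_grid_refinement(self, embryo_fb):
        readouts = []
        for nc in (54, 108):
            g = Grid1D(n_cells=nc)
            init = make_initial_profile("polarized", g, K_P=embryo_fb.K_P,
                                        amplitude=0.25, ratio=8.0)
            readouts.append(simulate_maintenance(init, embryo_fb,
                                                 t_sim=240.0).asymmetry)
        assert abs(readouts[1] / readouts[0] - 1) < 0.01

    def test_lpa_bistability_implies_pde_polarized_state(self, grid):
        # spot-check: LPA-bistable cells support a stable polarized PDE
        # profile from a step initial condition
        cells = [(14.5, 62.0), (20.0, 40.0), (8.0, 80.0), (30.0, 30.0),
                 (10.0, 62.0)]
        for kf, kp in cells:
            fb = calibrate(FeedbackParameters(K_f=kf, K_P=kp))
            if lpa_classify(fb).label != "inducible_polarity":
                continue
            init = make_initial_profile("polarized", grid, K_P=fb.K_P,
                                        amplitude=0.2, ratio=8.0, width=0.3)
            res = simulate_maintenance(init, fb, t_sim=240.0)
            assert res.asymmetry > 2.0

    def test_determinism_of_readout_json(self, embryo_fb, polarized_init):
        outs = []
        for _ in range(2):
            res = simulate_maintenance(polarized_init, embryo_fb, t_sim=60.0)
            outs.append(json.dumps({"asym": res.asymmetry,
                                    "rr": res.recruitment_ratio,
                                    "s": res.mean_size_anterior},
                                   sort_keys=True))
        assert outs[0] == outs[1]


@pytest.fixture(scope="module")
def scan(embryo_fb, polarized_init):
    totals = np.array([1.0, 0.3, 0.02])
    return depletion_response(embryo_fb, polarized_init, totals,
                              bias_ratio=1.78)


class TestDepletionResponse:
    def test_variants_coincide_at_reference(self, scan):
        ref = scan[scan.total == 1.0].set_index("variant")
        assert ref.loc["feedback", "asymmetry"] == pytest.approx(
            ref.loc["fixed_bias", "asymmetry"], rel=0.02)

    def test_feedback_collapses_below_threshold(self, scan):
        fb_rows = scan[scan.variant == "feedback"].sort_values("total")
        assert fb_rows.iloc[0].asymmetry == pytest.approx(1.0, abs=0.02)

    def test_fixed_bias_asymptote_is_bias_ratio(self, scan):
        bias_rows = scan[scan.variant == "fixed_bias"].sort_values("total")
        low = bias_rows.iloc[0]
        assert low.mean_size < 1.05
        assert low.asymmetry == pytest.approx(1.78, rel=0.02)

    def test_totals_must_descend(self, embryo_fb, polarized_init):
        with pytest.raises(KineticsError):
            depletion_response(embryo_fb, polarized_init,
                               np.array([0.5, 1.0]))


@pytest.fixture(scope="module")
def attractor(control_run):
    return control_run.final


class TestPerturbationScenarios:
    def test_control_preserves_asymmetry(self, embryo_fb, attractor):
        res = perturbation_scenarios(embryo_fb, "control", attractor)
        a0 = attractor.asymmetry()
        assert abs(res.asymmetry / a0 - 1) < 0.10

    def test_no_feedback_decay_incomplete(self, embryo_fb, attractor):
        res = perturbation_scenarios(embryo_fb, "no_feedback", attractor)
        asym = res.anterior_mean / res.posterior_mean
        # decay sets in after a brief re-equilibration of the size structure
        assert np.all(np.diff(asym[2:]) < 0)
        assert 1.0 < asym[-1] < asym[0]

    def test_cdc42_posterior_rises(self, embryo_fb, attractor):
        res = perturbation_scenarios(embryo_fb, "cdc42_mimic", attractor)
        assert np.all(np.diff(res.posterior_mean) > 0)

    def test_unknown_scenario(self, embryo_fb, attractor):
        with pytest.raises(KineticsError):
            perturbation_scenarios(embryo_fb, "nonsense", attractor)

    def test_scenario_table_complete(self):
        assert {"control", "no_feedback", "cdc42_mimic"} <= \
            set(PERTURBATION_SCENARIOS)
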