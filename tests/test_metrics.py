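import math

import numpy as np
import pytest

from gravitropism import (DoseResponseCurve, InvalidParameterError, Regime,
                          TipTrajectory, asymptotic_sensitivity,
                          classify_regime, crossover_gravity,
                          dose_response_curve, gravitropic_sensitivity,
                          phase_diagram, simulate_transient)


def _ramp_trajectory(k=0.1, n=101):
    """Linear counter-bending ramp theta_tip = -k*t at fixed vertical base."""
    t = np.linspace(0.0, 50.0, n)
    return TipTrajectory(t=t, theta_tip=-k * t, theta_base=np.zeros(n))


class TestGravitropicSensitivity:
    def test_flat_trajectory_returns_zero_with_warning(self, wheat):
        t = np.linspace(0, 100, 50)
        traj = TipTrajectory(t=t, theta_tip=np.zeros(50), theta_base=np.zeros(50))
        with pytest.warns(UserWarning, match="flat"):
            assert gravitropic_sensitivity(traj, wheat, 45.0) == 0.0

    def test_zero_inclination_rejected(self, wheat):
        with pytest.raises(InvalidParameterError):
            gravitropic_sensitivity(_ramp_trajectory(), wheat, 0.0)

    def test_analytic_ramp(self, wheat):
        """theta_tip = k*t gives beta_tilde = R*k/(sin(45) * eps_dot * L)."""
        k = 0.1  # deg/min
        bt = gravitropic_sensitivity(_ramp_trajectory(k), wheat, 45.0)
        expected = (wheat.R * math.radians(k)
                    / (math.sin(math.radians(45.0)) * wheat.elongation_velocity))
        assert bt == pytest.approx(expected, rel=1e-6)

    def test_sign_convention_symmetric_in_inclination(self, wheat):
        traj = simulate_transient(wheat, 20.0, -45.0)
        bt_neg = gravitropic_sensitivity(traj, wheat, -45.0)
        traj_pos = simulate_transient(wheat, 20.0, 45.0)
        bt_pos = gravitropic_sensitivity(traj_pos, wheat, 45.0)
        assert bt_neg == pytest.approx(bt_pos, rel=1e-9)
        assert bt_neg > 0

    def test_independent_of_inclination_angle_for_permanent_stimulus(self, wheat):
        """The sine normalization removes the angle dependence (within 5%)."""
        values = []
        for theta in (30.0, 45.0, 60.0):
            traj = simulate_transient(wheat, math.inf, theta)
            values.append(gravitropic_sensitivity(traj, wheat, theta))
        assert max(values) / min(values) - 1.0 < 0.05


class TestDoseResponse:
    def test_monotone_and_saturating(self, wheat):
        """beta_tilde nondecreasing in dt; the long-stimulus limit matches
        the permanent-inclination value within 1%."""
        curve = dose_response_curve(wheat, [3.0, 8.0, 11.0, 20.0, math.inf])
        bt = curve.beta_tilde
        assert np.all(np.diff(bt) >= -1e-12)
        permanent = bt[-1]
        long_dt = dose_response_curve(wheat, [100.0 * wheat.tau_memory])
        assert long_dt.beta_tilde[0] == pytest.approx(permanent, rel=0.01)

    def test_memory_dose_slope_under_scale_separation(self, wheat):
        """With tau_aval << dt << tau_memory the initial slope of the dose
        curve approaches beta/tau_memory (within 10%)."""
        p = wheat.replace(tau_aval_ref=0.02)
        d = 0.5
        curve = dose_response_curve(p, [d])
        slope = curve.beta_tilde[0] / d
        assert slope == pytest.approx(p.beta / p.tau_memory, rel=0.10)

    def test_gravity_invariance_under_scale_separation(self, wheat):
        """For tau_aval << tau_memory the dose curves at 1g and 3g agree
        within 2% pointwise (the avalanche is no longer limiting)."""
        p = wheat.replace(tau_aval_ref=0.13)
        dts = [3.0, 8.0, 20.0]
        c1 = dose_response_curve(p, dts, g_eff=1.0)
        c3 = dose_response_curve(p, dts, g_eff=3.0)
        assert np.max(np.abs(c3.beta_tilde / c1.beta_tilde - 1.0)) < 0.02

    def test_rejects_bad_dt_list(self, wheat):
        with pytest.raises(InvalidParameterError):
            dose_response_curve(wheat, [])
        with pytest.raises(InvalidParameterError):
            dose_response_curve(wheat, [5.0, -1.0])


class TestRegimes:
    def test_calibrated_wheat_experimental_conditions(self, wheat):
        label, _ = classify_regime(1.04, 5.0, wheat)
        assert label is Regime.MEMORY_DOSE

    def test_steady_inclination_is_sine_law(self, wheat):
        label, _ = classify_regime(1.04, 1e4, wheat)
        assert label is Regime.SATURATED_SINE

    def test_low_gravity_short_stimulus_is_avalanche_dose(self, wheat):
        label, _ = classify_regime(1e5, 10.0, wheat)
        assert label is Regime.AVALANCHE_DOSE

    def test_all_four_regimes_occur_on_wide_grid(self, wheat):
        tau_grid = np.geomspace(1e-1, 1e5, 25)
        dt_grid = np.geomspace(1.0, 1e5, 25)
        seen = {classify_regime(ta, d, wheat)[0]
                for ta in tau_grid for d in dt_grid}
        assert seen == set(Regime)

    def test_boundary_flag_near_crossings(self, wheat):
        _, flag = classify_regime(wheat.tau_memory * 1.1, 5.0, wheat)
        assert flag
        _, flag_deep = classify_regime(1e4, 10.0, wheat)
        assert not flag_deep

    @pytest.mark.parametrize("tau_aval,dt,regime,expected", [
        (0.1, 5.0, Regime.MEMORY_DOSE, 0.8 * 5.0 / 13.0),
        (0.1, 1e4, Regime.SATURATED_SINE, 0.8),
        (1e4, 100.0, Regime.AVALANCHE_DOSE, 0.8 * 100.0 / 1e4),
        (1e4, 2e4, Regime.GROWTH_LIMITED, 0.8 * math.sqrt(60.0 / 1e4)),
    ])
    def test_asymptotic_formulas(self, wheat, tau_aval, dt, regime, expected):
        est, label, _ = asymptotic_sensitivity(wheat, dt, tau_aval=tau_aval)
        assert label is regime
        assert est == pytest.approx(expected, rel=1e-12)

    def test_crossover_gravity_levels(self, wheat):
        g_mem, g_growth = crossover_gravity(wheat)
        assert g_mem == pytest.approx(1.04 / 13.0)
        assert g_growth == pytest.approx(1.04 / 1200.0)
        unit = wheat.replace(tau_aval_ref=13.0)
        assert crossover_gravity(unit)[0] == pytest.approx(1.0)


class TestPhaseDiagram:
    def test_small_grid_labels_and_shape(self, wheat):
        """A coarse sweep carries one finite sensitivity and one regime
        label per cell, and the dt=5 slice is flat then decaying in
        tau_aval (the hypogravity transition)."""
        tau_grid = np.array([0.1, 1.04, 1e3, 1e5])
        dt_grid = np.array([5.0, 200.0])
        diagram = phase_diagram(wheat, tau_grid, dt_grid, n_nodes=32)
        assert diagram.beta_tilde.shape == (2, 4)
        assert np.all(np.isfinite(diagram.beta_tilde))
        assert all(isinstance(r, Regime) for r in diagram.regime.ravel())
        # dt = 5 min slice: gravity-independent plateau for fast avalanches,
        # then beta*dt/tau_aval decay once the avalanche is limiting
        slice5 = diagram.beta_tilde[0]
        assert slice5[0] == pytest.approx(slice5[1], rel=0.10)
        assert slice5[2] == pytest.approx(0.8 * 5.0 / 1e3, rel=0.05)
        assert slice5[3] / slice5[2] == pytest.approx(1e-2, rel=0.15)
        frame = diagram.to_frame()
        assert set(frame.columns) == {"tau_aval_min", "dt_min",
                                      "beta_tilde", "regime"}
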