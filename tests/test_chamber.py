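"""Forward chamber model against closed forms and independent integrators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import flowbind as fb
from flowbind.chamber import (
    _model_args,
    _rhs,
    apply_dead_time,
    correct_dead_time,
    dead_time_for_loss,
    replacement_time,
)
from flowbind.core import InvalidParameterError, Phase, replace

NO_BINDING = fb.KineticParams(k_on=1.0, k_off=0.0, n_antigens_total=0.0)


class TestCstrMixing:
    @pytest.mark.parametrize("engine", ["adaptive", "rk4"])
    def test_step_response_closed_form(self, config, calib, engine):
        """With no receptors, total ligand follows the CSTR step
        L(t) = C0 * (1 - exp(-Q t / V)); at t = V/Q it reaches 63.2%."""
        tau = config.volume_L / config.flow_L_s
        assert tau == pytest.approx(180.0)
        t = np.array([0.0, tau, 600.0, 3600.0])
        traj = fb.simulate(config, calib, NO_BINDING, t_grid=t, engine=engine)
        total = traj.L_reactive_M + traj.L_inert_M
        expected = config.inflow_molar_M * (1 - np.exp(-t / tau))
        np.testing.assert_allclose(total[1:], expected[1:], rtol=1e-6)
        assert total[1] == pytest.approx(0.632 * config.inflow_molar_M, rel=1e-3)

    def test_replacement_times_match_flush_measurements(self):
        """99% replacement: 13.0 min at 3.4 mL/h and 7.4 min at 6 mL/h for
        the 0.16 mL cuvette, as observed when switching liquids."""
        assert replacement_time(3.4, 0.16, 0.99) / 60 == pytest.approx(13.0, abs=0.05)
        assert replacement_time(6.0, 0.16, 0.99) / 60 == pytest.approx(7.4, abs=0.05)

    def test_replacement_time_constant_fraction(self):
        q, v = 3.2, 0.16
        assert replacement_time(q, v, 1 - 1 / np.e) == pytest.approx(
            v / q * 3600, rel=1e-12
        )

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.5, 1.5])
    def test_replacement_fraction_domain(self, fraction):
        with pytest.raises(InvalidParameterError):
            replacement_time(3.2, 0.16, fraction)


class TestBindingKinetics:
    def test_pseudo_first_order_limit(self, calib):
        """Excess constant ligand, k_off = 0: B(t) = R_tot (1 - e^(-k_on L t)).

        High flow makes mixing instantaneous and a tiny receptor pool makes
        depletion negligible, isolating the binding exponential.
        """
        config = fb.AssayConfig(flow_rate_mL_h=600.0, irf=1.0)
        params = fb.KineticParams(k_on=4.5e4, k_off=0.0, n_antigens_total=1e9)
        t = np.array([1800.0, 3600.0, 7200.0, 10800.0])
        traj = fb.simulate(config, calib, params, t_grid=t)
        L = config.inflow_molar_M
        expected = params.r_tot_mol * (1 - np.exp(-params.k_on * L * t))
        np.testing.assert_allclose(traj.B_mol, expected, rtol=2e-3)

    def test_equilibrium_law(self, calib):
        """At steady state B = R_tot * L / (L + K_d), with L equal to the
        inflow concentration (no net consumption at equilibrium)."""
        config = fb.AssayConfig(
            flow_rate_mL_h=60.0, irf=1.0, phases=(Phase(60000.0, "radioligand"),)
        )
        params = fb.KineticParams(k_on=4.5e4, k_off=1e-4, n_antigens_total=1.1e12)
        L = config.inflow_molar_M
        k_obs = params.k_on * L + params.k_off
        t_end = np.ceil(np.log(1e5) / k_obs / 60) * 60  # well past equilibration
        traj = fb.simulate(config, calib, params, t_grid=np.array([0.0, t_end]))
        b_eq = params.r_tot_mol * L / (L + params.k_d)
        assert traj.B_mol[-1] == pytest.approx(b_eq, rel=1e-4)

    def test_no_receptors_no_binding(self, config, calib):
        traj = fb.simulate(config, calib, NO_BINDING)
        assert np.all(traj.B_mol == 0.0)
        assert np.all(traj.A_bound_kBq == 0.0)

    def test_bound_never_exceeds_receptor_pool(self, config, calib, truth):
        traj = fb.simulate(config, calib, truth)
        assert np.all(traj.B_mol <= truth.r_tot_mol * (1 + 1e-9))
        assert np.all(traj.B_mol >= 0)

    def test_washout_with_zero_koff_conserves_bound(self, calib, truth):
        """With k_off = 0 (and no decay) the bound activity is constant in
        washout once residual chamber ligand has flushed out (the first
        ~15 min of washout still feed binding from the CSTR tail)."""
        config = fb.AssayConfig()
        params = replace(truth, k_off=0.0)
        t = np.array([4 * 3600.0, 4.5 * 3600.0, 5 * 3600.0])
        traj = fb.simulate(config, calib, params, t_grid=t)
        np.testing.assert_allclose(traj.A_bound_kBq, traj.A_bound_kBq[0], rtol=1e-9)
        # and it never decreases anywhere in the run
        full = fb.simulate(config, calib, params)
        assert np.all(np.diff(full.A_bound_kBq) >= -1e-12 * full.A_bound_kBq.max())

    def test_decay_scales_bound_activity_not_moles(self, calib, truth):
        config = fb.AssayConfig(half_life_s=7.2 * 3600.0)  # astatine-211
        config0 = fb.AssayConfig()
        t = np.array([3600.0, 10800.0])
        with_decay = fb.simulate(config, calib, truth, t_grid=t)
        without = fb.simulate(config0, calib, truth, t_grid=t)
        dec = fb.core.decay_factor(t, 7.2 * 3600.0)
        np.testing.assert_allclose(
            with_decay.A_bound_kBq, without.A_bound_kBq * dec, rtol=1e-4
        )


class TestNumerics:
    def test_mass_balance(self, config, calib, truth):
        """Cumulative inflow - outflow - chamber content - bound content
        vanishes at every output time."""
        for engine in ("adaptive", "rk4"):
            traj = fb.simulate(config, calib, truth, engine=engine)
            resid = traj.mass_balance_residual(config)
            assert np.max(np.abs(resid[1:])) < 1e-6

    def test_engines_agree(self, config, calib, truth):
        a = fb.predict_channel_signals(config, calib, truth, engine="adaptive")
        b = fb.predict_channel_signals(config, calib, truth, engine="rk4")
        np.testing.assert_allclose(a.true_counts, b.true_counts, rtol=1e-6)
        np.testing.assert_allclose(a.observed_counts, b.observed_counts, rtol=1e-6)

    def test_adaptive_agrees_with_euler_oracle(self, calib, truth):
        """Fixed-step explicit-Euler at 10 ms steps over a 1 h uptake
        reproduces the adaptive solution to 1e-4 relative."""
        config = fb.AssayConfig(phases=(Phase(3600.0, "radioligand"),))
        args = _model_args(config, calib, truth)
        c_in = config.inflow_molar_M
        lr_in, li_in = config.irf * c_in, (1 - config.irf) * c_in
        dt = 0.01
        n = int(3600 / dt)
        y = np.zeros(8)
        dy = np.empty(8)
        for i in range(n):
            _rhs(i * dt, y, lr_in, li_in, *args, dy)
            y = y + dt * dy
        traj = fb.simulate(config, calib, truth, t_grid=np.array([3600.0]))
        assert y[0] == pytest.approx(traj.L_reactive_M[0], rel=1e-4)
        assert y[1] == pytest.approx(traj.L_inert_M[0], rel=1e-4)
        assert y[2] == pytest.approx(traj.B_mol[0], rel=1e-4)

    def test_channel_integration_handles_midchannel_switch(self, calib, truth):
        """A transport delay placing the inflow switch mid-channel must be
        integrated exactly, not midpoint-approximated."""
        config = fb.AssayConfig(transport_delay_s=30.0)
        a = fb.predict_channel_signals(config, calib, truth, engine="adaptive")
        b = fb.predict_channel_signals(config, calib, truth, engine="rk4")
        np.testing.assert_allclose(a.true_counts, b.true_counts, rtol=1e-6)
        # the switch channel sees only the post-delay sliver of the rising
        # inflow signal, far below the near-plateau later channels
        assert 0.0 < a.solution_counts[0] < 0.3 * a.solution_counts[5]

    def test_grid_outside_schedule_rejected(self, config, calib, truth):
        with pytest.raises(InvalidParameterError):
            fb.simulate(config, calib, truth, t_grid=np.array([0.0, 1e6]))


class TestDeadTime:
    def test_calibrated_loss_at_peak_rate(self):
        """tau solving a 2.5% non-paralyzable loss at 1600 cps: observed
        rate 1560 cps."""
        tau = dead_time_for_loss(0.025, 1600.0)
        assert tau == pytest.approx(1.603e-5, rel=1e-3)
        assert apply_dead_time(1600.0, tau) == pytest.approx(1560.0, rel=1e-9)

    def test_zero_dead_time_identity(self):
        assert apply_dead_time(1234.5, 0.0) == 1234.5
        assert correct_dead_time(1234.5, 0.0) == 1234.5

    @given(rate=st.floats(0.0, 5e4), tau=st.floats(0.0, 2e-5))
    def test_round_trip_and_bounds(self, rate, tau):
        observed = apply_dead_time(rate, tau)
        assert observed <= rate
        assert correct_dead_time(observed, tau) == pytest.approx(rate, rel=1e-9, abs=1e-9)

    @given(tau=st.floats(1e-7, 2e-5), r1=st.floats(0, 1e4), r2=st.floats(0, 1e4))
    def test_monotone_in_true_rate(self, tau, r1, r2):
        lo, hi = sorted([r1, r2])
        assert apply_dead_time(lo, tau) <= apply_dead_time(hi, tau)

    def test_saturation_rejected(self):
        with pytest.raises(InvalidParameterError):
            correct_dead_time(1e5, 1e-4)
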