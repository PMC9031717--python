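import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from emca.thermal import (
    CalibrationCorrection,
    ClosedLoopTrace,
    FOPDTModel,
    PIGains,
    PWMActuator,
    RampProtocol,
    StepResponse,
    ThermalError,
    fit_calibration,
    identify_fopdt,
    pi_controller_output,
    simulate_closed_loop,
    simulate_step_response,
    step_metrics,
)


class TestFOPDTModel:
    def test_invariants(self):
        with pytest.raises(ThermalError):
            FOPDTModel(gain=0.0, time_constant=10.0)
        with pytest.raises(ThermalError):
            FOPDTModel(gain=1.0, time_constant=0.0)
        with pytest.raises(ThermalError):
            FOPDTModel(gain=1.0, time_constant=10.0, dead_time=-1.0)
        with pytest.raises(ThermalError):
            FOPDTModel(gain=float("inf"), time_constant=10.0)


class TestStepResponseSim:
    def test_first_order_closed_form(self):
        m = FOPDTModel(gain=2.0, time_constant=10.0, dead_time=0.0, ambient=25.0)
        r = simulate_step_response(m, 1.0, 60.0, 0.5)
        # T(10) = 25 + 2*(1 - e^-1)
        assert r.temperatures[20] == pytest.approx(25.0 + 2.0 * (1 - math.exp(-1)), abs=1e-12)

    def test_dead_time_holds_ambient(self):
        m = FOPDTModel(gain=2.0, time_constant=10.0, dead_time=5.0, ambient=25.0)
        r = simulate_step_response(m, 1.0, 60.0, 0.25)
        pre = r.temperatures[r.times < 5.0 - 1e-12]
        assert np.all(pre == 25.0)

    def test_steady_state_gain(self):
        m = FOPDTModel(gain=-3.0, time_constant=4.0, dead_time=1.0, ambient=30.0)
        r = simulate_step_response(m, 2.0, 200.0, 0.5)
        assert r.temperatures[-1] == pytest.approx(30.0 - 6.0, abs=1e-6)

    def test_closed_form_everywhere_noise_free(self):
        m = FOPDTModel(gain=1.7, time_constant=8.0, dead_time=2.0, ambient=22.0)
        r = simulate_step_response(m, 3.0, 80.0, 0.1)
        expected = np.where(
            r.times >= 2.0,
            22.0 + 1.7 * 3.0 * (1 - np.exp(-(r.times - 2.0) / 8.0)),
            22.0,
        )
        np.testing.assert_allclose(r.temperatures, expected, atol=1e-10)

    def test_noise_reproducible(self):
        m = FOPDTModel(gain=1.0, time_constant=10.0)
        a = simulate_step_response(m, 1.0, 60.0, 0.5, noise_sd=0.1, seed=7)
        b = simulate_step_response(m, 1.0, 60.0, 0.5, noise_sd=0.1, seed=7)
        np.testing.assert_array_equal(a.temperatures, b.temperatures)

    def test_errors(self):
        m = FOPDTModel(gain=1.0, time_constant=10.0, dead_time=5.0)
        with pytest.raises(ThermalError):
            simulate_step_response(m, 1.0, 60.0, sample_interval=0.0)
        with pytest.raises(ThermalError):
            simulate_step_response(m, 1.0, 4.0, sample_interval=0.1)

    def test_step_response_validation(self):
        with pytest.raises(ThermalError):
            StepResponse(np.arange(20.0), np.zeros(20), step_magnitude=0.0)
        with pytest.raises(ThermalError):
            StepResponse(np.arange(5.0), np.zeros(5), step_magnitude=1.0)


class TestIdentify:
    def test_exact_on_true_fopdt(self):
        m = FOPDTModel(gain=1.5, time_constant=12.0, dead_time=3.0, ambient=25.0)
        r = simulate_step_response(m, 1.0, 3.0 + 30 * 12.0, 0.01)
        est = identify_fopdt(r)
        assert est.gain == pytest.approx(1.5, rel=1e-9)
        assert est.time_constant == pytest.approx(12.0, abs=0.01)
        assert est.dead_time == pytest.approx(3.0, abs=0.01)

    def test_gain_is_rise_over_step(self):
        m = FOPDTModel(gain=3.0, time_constant=10.0, dead_time=0.0, ambient=25.0)
        r = simulate_step_response(m, 3.0, 300.0, 0.1)
        est = identify_fopdt(r)
        assert r.temperatures[-1] - r.temperatures[0] == pytest.approx(9.0, abs=1e-4)
        assert est.gain == pytest.approx(3.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_tau_vs_least_squares_oracle(self, seed):
        """Independent oracle: full-curve nonlinear least squares.  A 10 s
        pre-step baseline is recorded, as in a real identification run."""
        m = FOPDTModel(gain=1.5, time_constant=12.0, dead_time=3.0, ambient=25.0)
        r = simulate_step_response(
            m, 3.0, 160.0, 0.05, noise_sd=0.1, seed=seed, step_time=10.0
        )
        est = identify_fopdt(r, noise_sd=0.1)

        def resid(p):
            gain, tau, theta, amb = p
            y = amb + gain * 3.0 * np.where(
                r.times > 10.0 + theta,
                1.0 - np.exp(-(r.times - 10.0 - theta) / max(tau, 1e-9)),
                0.0,
            )
            return y - r.temperatures

        oracle = least_squares(resid, x0=[1.0, 10.0, 1.0, 24.0]).x
        assert est.time_constant == pytest.approx(oracle[1], rel=0.05)
        assert est.time_constant == pytest.approx(12.0, rel=0.05)

    def test_plateau_not_reached(self):
        m = FOPDTModel(gain=1.5, time_constant=50.0, dead_time=0.0, ambient=25.0)
        r = simulate_step_response(m, 1.0, 60.0, 0.1)  # just over one tau
        with pytest.raises(ThermalError, match="plateau"):
            identify_fopdt(r)

    def test_non_monotone_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        y = 25.0 + 5.0 * (1 - np.exp(-t / 5.0))
        y[60:80] -= 2.0  # a dip far beyond noise
        with pytest.raises(ThermalError, match="non-monotone"):
            identify_fopdt(StepResponse(t, y, 1.0))

    def test_round_trip_random_plants(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            tau = rng.uniform(5.0, 200.0)
            theta = rng.uniform(0.0, 30.0)
            gain = rng.uniform(0.5, 40.0)
            dt = tau / 100.0
            m = FOPDTModel(gain=gain, time_constant=tau, dead_time=theta, ambient=25.0)
            r = simulate_step_response(m, 1.0, theta + 30 * tau, dt)
            est = identify_fopdt(r)
            assert est.gain == pytest.approx(gain, rel=1e-9)
            assert abs(est.time_constant - tau) <= dt
            assert abs(est.dead_time - theta) <= dt


class TestPIController:
    def test_zero_error(self):
        g = PIGains(proportional=10.0, integral=2.0)
        assert pi_controller_output(0.0, 0.0, g) == 0.0

    def test_published_gains_unit_error(self):
        g = PIGains(proportional=55.85, integral=1.33)
        assert pi_controller_output(1.0, 0.0, g) == pytest.approx(55.85)

    def test_integral_linearity(self):
        g = PIGains(proportional=0.0, integral=1.33)
        assert pi_controller_output(0.0, 2.0, g) == pytest.approx(2.66)

    def test_nonfinite_rejected(self):
        g = PIGains(proportional=1.0, integral=1.0)
        with pytest.raises(ThermalError):
            pi_controller_output(float("nan"), 0.0, g)

    def test_negative_gains_rejected(self):
        with pytest.raises(ThermalError):
            PIGains(proportional=-1.0, integral=0.0)


class TestPWMActuator:
    def test_levels(self):
        a = PWMActuator(bits=10, full_scale=5.0)
        q = 5.0 / 1023
        assert a.quantize(0.0) == 0.0
        assert a.quantize(5.0) == pytest.approx(5.0)
        assert a.quantize(2.5) % q == pytest.approx(0.0, abs=1e-12)
        assert a.quantize(7.0) == pytest.approx(5.0)  # clamped
        assert a.quantize(-1.0) == 0.0

    def test_emitted_levels_are_grid_multiples(self):
        a = PWMActuator(bits=4, full_scale=5.0)
        q = 5.0 / 15
        for u in np.linspace(-1, 6, 57):
            k = a.quantize(u) / q
            assert k == pytest.approx(round(k), abs=1e-9)
            assert 0 <= round(k) <= 15

    def test_bad_bits(self):
        with pytest.raises(ThermalError):
            PWMActuator(bits=0)


class TestClosedLoop:
    def test_integral_action_up_to_quantum(self):
        m = FOPDTModel(gain=2.0, time_constant=20.0, dead_time=0.0, ambient=25.0)
        act = PWMActuator(bits=10, full_scale=10.0)
        tr = simulate_closed_loop(
            m, PIGains(2.0, 0.5), act, lambda t: 40.0, 600.0, 0.1
        )
        bound = m.gain * act.quantum
        assert abs(tr.plate_temperatures[-1] - 40.0) <= bound + 1e-9

    def test_no_quantization_zero_steady_state_error(self):
        m = FOPDTModel(gain=2.0, time_constant=20.0, dead_time=0.0, ambient=25.0)
        tr = simulate_closed_loop(
            m, PIGains(2.0, 0.5), None, lambda t: 40.0, 800.0, 0.1
        )
        assert abs(tr.plate_temperatures[-1] - 40.0) < 1e-3

    def test_zero_gains_stay_at_ambient(self):
        m = FOPDTModel(gain=2.0, time_constant=20.0, dead_time=0.0, ambient=25.0)
        tr = simulate_closed_loop(
            m, PIGains(0.0, 0.0), PWMActuator(), lambda t: 60.0, 100.0, 0.1
        )
        np.testing.assert_allclose(tr.plate_temperatures, 25.0, atol=1e-12)

    def test_published_gains_track_ramp_without_exceeding(self):
        from emca.config import DEMO_PLANT, PUBLISHED_GAINS, default_actuator

        ramp = RampProtocol(start=25.0, end=90.0, step=1.0, dwell=30.0)
        tr = simulate_closed_loop(
            DEMO_PLANT, PUBLISHED_GAINS, default_actuator(), ramp.setpoint,
            ramp.duration, 0.05,
        )
        excess = tr.plate_temperatures - tr.setpoints
        assert excess.max() <= 0.0
        assert (-excess).max() < 3.0  # tracks within a few degC of the stairs

    def test_divergence_diagnostic_names_gains(self):
        # enormous loop gain with a long dead time destabilizes the loop
        m = FOPDTModel(gain=50.0, time_constant=2.0, dead_time=1.0, ambient=25.0)
        with pytest.raises(RuntimeError, match="Kc=400"):
            simulate_closed_loop(
                m, PIGains(400.0, 50.0), None, lambda t: 125.0, 2000.0, 0.1
            )

    def test_reproducible_with_seed(self):
        m = FOPDTModel(gain=2.0, time_constant=20.0, dead_time=0.5, ambient=25.0)
        kw = dict(noise_sd=0.05, seed=11)
        a = simulate_closed_loop(m, PIGains(3.0, 0.2), PWMActuator(), lambda t: 35.0, 60.0, 0.1, **kw)
        b = simulate_closed_loop(m, PIGains(3.0, 0.2), PWMActuator(), lambda t: 35.0, 60.0, 0.1, **kw)
        np.testing.assert_array_equal(a.plate_temperatures, b.plate_temperatures)
        np.testing.assert_array_equal(a.controller_outputs, b.controller_outputs)

    def test_slide_lag_follows_plate(self):
        m = FOPDTModel(gain=2.0, time_constant=10.0, dead_time=0.0, ambient=25.0)
        lag = FOPDTModel(gain=1.0, time_constant=30.0, dead_time=0.0, ambient=25.0)
        tr = simulate_closed_loop(
            m, PIGains(5.0, 0.5), None, lambda t: 40.0, 900.0, 0.1, slide_lag=lag
        )
        assert tr.slide_temperatures is not None
        # the slide lags behind on the way up but converges to the plate
        assert tr.slide_temperatures[100] < tr.plate_temperatures[100]
        assert tr.slide_temperatures[-1] == pytest.approx(
            tr.plate_temperatures[-1], abs=0.05
        )


def _second_order_trace(zeta, dt=0.005):
    """Closed loop that is exactly second order: pure integral control on a
    dead-time-free first-order plant (no zero in the transfer function)."""
    gain, tau = 1.0, 10.0
    ki = 1.0 / (4.0 * zeta**2 * gain * tau)
    wn = math.sqrt(ki * gain / tau)
    plant = FOPDTModel(gain=gain, time_constant=tau, dead_time=0.0, ambient=25.0)
    duration = 30.0 / (zeta * wn)
    return simulate_closed_loop(
        plant, PIGains(0.0, ki), None,
        lambda t: 35.0 if t >= 5.0 else 25.0, duration, dt,
    )


class TestStepMetrics:
    @pytest.mark.parametrize("zeta", [0.3, 0.45, 0.584, 0.75, 0.9])
    def test_overshoot_matches_second_order_formula(self, zeta):
        tr = _second_order_trace(zeta)
        pred = 100.0 * math.exp(-math.pi * zeta / math.sqrt(1 - zeta**2))
        mets = step_metrics(tr)
        assert mets.overshoot == pytest.approx(pred, abs=2.0)

    def test_zeta_0584_gives_10_4_pct_overshoot(self):
        # damping ratio 0.584 corresponds to ~10.4% overshoot
        tr = _second_order_trace(0.584)
        assert step_metrics(tr).overshoot == pytest.approx(10.4, abs=0.5)

    def test_overdamped_zero_overshoot(self):
        m = FOPDTModel(gain=1.0, time_constant=5.0, dead_time=0.0, ambient=25.0)
        tr = simulate_closed_loop(
            m, PIGains(10.0, 0.2), None,
            lambda t: 35.0 if t >= 2.0 else 25.0, 600.0, 0.01,
        )
        mets = step_metrics(tr)
        assert mets.overshoot == 0.0
        assert mets.rise_time > 0.0

    def test_offset_and_time_shift_invariance(self):
        tr = _second_order_trace(0.5)
        base = step_metrics(tr)
        shifted = ClosedLoopTrace(
            times=tr.times + 123.0,
            setpoints=tr.setpoints + 40.0,
            plate_temperatures=tr.plate_temperatures + 40.0,
            controller_outputs=tr.controller_outputs,
        )
        other = step_metrics(shifted)
        assert other.rise_time == pytest.approx(base.rise_time, abs=1e-9)
        assert other.settling_time == pytest.approx(base.settling_time, abs=1e-9)
        assert other.overshoot == pytest.approx(base.overshoot, abs=1e-9)

    def test_never_reaches_90pct(self):
        t = np.arange(0.0, 50.0, 0.5)
        sp = np.where(t >= 5.0, 35.0, 25.0)
        y = np.full_like(t, 25.0)
        with pytest.raises(ThermalError, match="90%"):
            step_metrics(ClosedLoopTrace(t, sp, y, np.zeros_like(t)))


class TestCalibration:
    def test_exact_line(self):
        r = np.linspace(20.0, 90.0, 15)
        ref = 0.97 * r + 1.2
        c = fit_calibration(r, ref)
        assert c.slope == pytest.approx(0.97, abs=1e-12)
        assert c.intercept == pytest.approx(1.2, abs=1e-10)

    def test_identity(self):
        r = np.array([20.0, 40.0, 60.0, 80.0])
        c = fit_calibration(r, r)
        assert c.slope == pytest.approx(1.0, abs=1e-12)
        assert c.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(20.0, 95.0, 100)
        ref = 1.02 * r - 0.7 + rng.normal(0.0, 0.3, 100)
        c = fit_calibration(r, ref)
        # closed-form normal equations
        X = np.column_stack([r, np.ones_like(r)])
        beta = np.linalg.solve(X.T @ X, X.T @ ref)
        assert c.slope == pytest.approx(beta[0], rel=1e-9)
        assert c.intercept == pytest.approx(beta[1], rel=1e-9)

    def test_degenerate_design(self):
        with pytest.raises(ThermalError):
            fit_calibration([30.0, 30.0, 30.0], [29.0, 30.0, 31.0])
        with pytest.raises(ThermalError):
            fit_calibration([30.0, 31.0], [30.0, 31.0])

    def test_apply(self):
        c = CalibrationCorrection(slope=0.97, intercept=1.2)
        assert c.apply(50.0) == pytest.approx(0.97 * 50.0 + 1.2)


class TestRampProtocol:
    def test_staircase(self):
        ramp = RampProtocol(start=25.0, end=95.0, step=1.0, dwell=30.0)
        assert ramp.n_steps == 70
        assert len(ramp.temperatures) == 71
        assert ramp.setpoint(0.0) == 25.0
        assert ramp.setpoint(29.9) == 25.0
        assert ramp.setpoint(30.0) == 26.0
        assert ramp.setpoint(1e9) == 95.0

    def test_validation(self):
        with pytest.raises(ThermalError):
            RampProtocol(start=95.0, end=25.0)
        with pytest.raises(ThermalError):
            RampProtocol(step=0.0)
        with pytest.raises(ThermalError):
            RampProtocol(dwell=0.5, sample_interval=1.0)
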