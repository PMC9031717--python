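"""Heating-plate simulation, identification and PI/PWM closed-loop control.

The heating plates are modelled as first-order-plus-dead-time (FOPDT)
processes.  A two-point method identifies the plant from a recorded step
response, and a discrete PI loop with PWM-quantized actuation drives the
plate through staircase temperature ramps.  Temperatures are degrees
Celsius at every interface.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "FOPDTModel",
    "StepResponse",
    "PIGains",
    "PWMActuator",
    "RampProtocol",
    "CalibrationCorrection",
    "ClosedLoopTrace",
    "StepMetrics",
    "simulate_step_response",
    "identify_fopdt",
    "pi_controller_output",
    "simulate_closed_loop",
    "step_metrics",
    "fit_calibration",
]


class ThermalError(ValueError):
    """Raised on invalid thermal-control inputs or unidentifiable data."""


@dataclass(frozen=True)
class FOPDTModel:
    """First-order-plus-dead-time plant.

    Parameters
    ----------
    gain : float
        Steady-state gain, degC per actuation unit.  Finite and nonzero.
    time_constant : float
        Time constant tau in seconds, > 0.
    dead_time : float
        Dead time theta in seconds, >= 0.
    ambient : float
        Temperature the plate relaxes to with zero actuation, degC.
    """

    gain: float
    time_constant: float
    dead_time: float = 0.0
    ambient: float = 25.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.gain) or self.gain == 0:
            raise ThermalError("gain must be finite and nonzero")
        if not self.time_constant > 0:
            raise ThermalError("time_constant must be > 0")
        if self.dead_time < 0:
            raise ThermalError("dead_time must be >= 0")


@dataclass(frozen=True)
class StepResponse:
    """Recorded open-loop response to an actuation step at ``step_time``."""

    times: np.ndarray
    temperatures: np.ndarray
    step_magnitude: float
    step_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise ThermalError("times and temperatures must be equal-length 1-D arrays")
        dt = np.diff(t)
        if len(dt) and (dt <= 0).any():
            raise ThermalError("times must be strictly increasing")
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ThermalError("times must lie on a uniform grid")
        if self.step_magnitude == 0:
            raise ThermalError("step_magnitude must be nonzero")
        if int(np.sum(t >= self.step_time)) < 10:
            raise ThermalError("need at least 10 samples after step_time")

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class PIGains:
    """PI controller gains: ``proportional`` (Kc, dimensionless) and
    ``integral`` (Ki, 1/s).  An optional derivative gain is accepted for
    completeness and defaults to 0 so the shipped behaviour is PI."""

    proportional: float
    integral: float
    derivative: float = 0.0

    def __post_init__(self) -> None:
        if self.proportional < 0 or self.integral < 0 or self.derivative < 0:
            raise ThermalError("controller gains must be >= 0")


@dataclass(frozen=True)
class PWMActuator:
    """b-bit PWM actuator emitting levels k*full_scale/(2^bits - 1)."""

    bits: int = 10
    full_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ThermalError("bits must be >= 1")
        if not self.full_scale > 0:
            raise ThermalError("full_scale must be > 0")

    @property
    def quantum(self) -> float:
        return self.full_scale / (2**self.bits - 1)

    def quantize(self, u: float) -> float:
        u = min(max(u, 0.0), self.full_scale)
        # floor(x + 0.5) rather than banker's rounding, for determinism
        return math.floor(u / self.quantum + 0.5) * self.quantum


@dataclass(frozen=True)
class RampProtocol:
    """Staircase setpoint ramp: hold ``start`` then climb ``step`` degC
    every ``dwell`` seconds until ``end``."""

    start: float = 25.0
    end: float = 95.0
    step: float = 1.0
    dwell: float = 30.0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ThermalError("ramp start must be below end")
        if not self.step > 0:
            raise ThermalError("ramp step must be > 0")
        if not (self.dwell >= self.sample_interval > 0):
            raise ThermalError("require dwell >= sample_interval > 0")

    @property
    def n_steps(self) -> int:
        return int(math.floor((self.end - self.start) / self.step + 1e-9))

    @property
    def temperatures(self) -> np.ndarray:
        """The dwell setpoints, start..end inclusive."""
        return self.start + self.step * np.arange(self.n_steps + 1)

    @property
    def duration(self) -> float:
        return self.dwell * (self.n_steps + 1)

    def setpoint(self, t: float) -> float:
        k = min(int(math.floor(t / self.dwell)), self.n_steps)
        return self.start + self.step * max(k, 0)


@dataclass(frozen=True)
class CalibrationCorrection:
    """Point-by-point linear reading correction: corrected = slope*r + intercept."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ThermalError("calibration slope must be nonzero")

    def apply(self, reading: float) -> float:
        return self.slope * reading + self.intercept


@dataclass
class ClosedLoopTrace:
    """Time series recorded by a closed-loop simulation."""

    times: np.ndarray
    setpoints: np.ndarray
    plate_temperatures: np.ndarray
    controller_outputs: np.ndarray
    slide_temperatures: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("setpoints", "plate_temperatures", "controller_outputs"):
            if len(getattr(self, name)) != n:
                raise ThermalError(f"{name} length mismatch")
        if self.slide_temperatures is not None and len(self.slide_temperatures) != n:
            raise ThermalError("slide_temperatures length mismatch")


@dataclass(frozen=True)
class StepMetrics:
    rise_time: float
    settling_time: float
    overshoot: float  # percent


def simulate_step_response(
    model: FOPDTModel,
    step_magnitude: float,
    duration: float,
    sample_interval: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    step_time: float = 0.0,
) -> StepResponse:
    """Open-loop response of ``model`` to an actuation step.

    Uses the exact discrete first-order update with a delay buffer of
    ``round(dead_time / sample_interval)`` samples, so with ``noise_sd = 0``
    the samples match T(t) = ambient + gain*u*(1 - exp(-(t - theta)/tau))
    for t >= theta.
    """
    if sample_interval <= 0:
        raise ThermalError("sample_interval must be > 0")
    if duration <= model.dead_time:
        raise ThermalError("duration must exceed the dead time")
    from scipy.signal import lfilter

    n = int(round(duration / sample_interval)) + 1
    times = np.arange(n) * sample_interval
    delay = int(round(model.dead_time / sample_interval))
    alpha = 1.0 - math.exp(-sample_interval / model.time_constant)
    u = np.where(times >= step_time, step_magnitude, 0.0)
    u_delayed = np.concatenate([np.zeros(delay), u])[: len(u)]
    target = model.ambient + model.gain * u_delayed
    # exact discrete first-order recursion T[k+1] = T[k] + alpha*(target[k]-T[k])
    y, _ = lfilter(
        [alpha], [1.0, -(1.0 - alpha)], target[:-1], zi=[(1.0 - alpha) * model.ambient]
    )
    temps = np.concatenate([[model.ambient], y])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, noise_sd, size=n)
    return StepResponse(times, temps, step_magnitude, step_time)


def _crossing_time(times: np.ndarray, temps: np.ndarray, level: float) -> float:
    """First time the response attains ``level``, linearly interpolated."""
    above = temps >= level
    if not above.any():
        raise ThermalError(f"response never attains level {level:.4g}")
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = temps[i - 1], temps[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def _clip_window(w: int, n: int) -> int:
    return min(max(w, 1), max(1, n // 8))


def _smoothed(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; raw values kept at the (biased) edges."""
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    half = window // 2
    out[:half] = y[:half]
    out[-half:] = y[-half:]
    return out


def identify_fopdt(
    response: StepResponse,
    noise_sd: float = 0.0,
    plateau_fraction: float = 0.1,
) -> FOPDTModel:
    """Two-point FOPDT identification from a step response.

    The process gain is the total temperature rise over the step
    magnitude.  With t283 and t632 the interpolated times (after the
    step) at which the response attains 28.3% and 63.2% of the rise,

        tau   = 1.5 * (t632 - t283)
        theta = max(0, t632 - tau)
    """
    t = response.times
    y = response.temperatures
    post = t >= response.step_time
    tp = t[post] - response.step_time
    yp = y[post]
    pre = y[~post]
    if pre.size:
        baseline = float(pre.mean())
    elif noise_sd > 0:
        # no pre-step record: average a short initial stretch so a single
        # noisy sample cannot skew the baseline (slight bias if theta ~ 0;
        # record pre-step data for unbiased identification)
        baseline = float(yp[: max(1, len(yp) // 100)].mean())
    else:
        baseline = float(yp[0])

    n_tail = max(4, int(math.ceil(plateau_fraction * len(yp))))
    tail = yp[-n_tail:]
    final = float(tail.mean())
    rise = final - baseline
    if rise == 0:
        raise ThermalError("no temperature rise: cannot identify")
    half = n_tail // 2
    drift = abs(float(tail[half:].mean()) - float(tail[:half].mean()))
    tol = max(3 * noise_sd * math.sqrt(2.0 / half), 1e-3 * abs(rise))
    if drift > tol:
        raise ThermalError("plateau not reached: tail still drifts")
    tol = max(3 * noise_sd, 1e-3 * abs(rise))
    sign = 1.0 if rise > 0 else -1.0
    # monotone-beyond-noise sanity check, in the direction of the rise
    z = sign * yp
    if np.max(np.maximum.accumulate(z) - z) > 5 * tol + 1e-12:
        raise ThermalError("response is non-monotone beyond noise")
    dt_s = float(tp[1] - tp[0]) if len(tp) > 1 else 1.0

    def crossing(fraction: float, window: int) -> float:
        y = _smoothed(yp, window)
        return _crossing_time(tp, sign * y, sign * (baseline + fraction * rise))

    if noise_sd > 0:
        # A raw first crossing is biased early (noise spikes cross the level
        # before the trend does), so locate crossings on a moving-average of
        # the data.  Stage 1: rough crossings with a window that leaves ~1%
        # of the rise in residual noise.  Stage 2: re-locate each crossing
        # with the window W* = (144 sigma^2 dt tau^4 / (rise (1-f))^2)^(1/5)
        # that balances residual-noise variance against the smoothing bias
        # from the exponential's curvature at that level.
        w1 = _clip_window(int(math.ceil((100.0 * noise_sd / abs(rise)) ** 2)), len(yp))
        tau_rough = 1.5 * max(crossing(0.632, w1) - crossing(0.283, w1), dt_s)

        def optimal_window(fraction: float) -> int:
            num = 144.0 * noise_sd**2 * dt_s * tau_rough**4
            den = (abs(rise) * (1.0 - fraction)) ** 2
            return _clip_window(int(round((num / den) ** 0.2 / dt_s)), len(yp))

        t283 = crossing(0.283, optimal_window(0.283))
        t632 = crossing(0.632, optimal_window(0.632))
    else:
        t283 = crossing(0.283, 1)
        t632 = crossing(0.632, 1)
    if t632 <= t283:
        raise ThermalError("63.2% crossing does not follow 28.3% crossing")
    tau = 1.5 * (t632 - t283)
    theta = max(0.0, t632 - tau)
    gain = rise / response.step_magnitude
    return FOPDTModel(gain=gain, time_constant=tau, dead_time=theta, ambient=baseline)


def pi_controller_output(error: float, error_integral: float, gains: PIGains) -> float:
    """Continuous PI law: Cout = Kc*e + Ki*integral(e)."""
    if not (math.isfinite(error) and math.isfinite(error_integral)):
        raise ThermalError("controller inputs must be finite")
    return gains.proportional * error + gains.integral * error_integral


def simulate_closed_loop(
    model: FOPDTModel,
    gains: PIGains,
    actuator: Optional[PWMActuator],
    setpoint_schedule: Callable[[float], float],
    duration: float,
    sample_interval: float = 0.1,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    slide_lag: Optional[FOPDTModel] = None,
    calibration: Optional[CalibrationCorrection] = None,
) -> ClosedLoopTrace:
    """Discrete PI loop around an FOPDT plate.

    Forward-Euler plant update; trapezoidal error integral with
    anti-windup (the integral is frozen while the actuator saturates);
    the controller output is quantized by ``actuator`` before entering
    the plant (``actuator=None`` gives an ideal continuous actuator,
    useful for linear-theory checks).  ``slide_lag`` filters the plate
    temperature through a second unity-style lag to model the glass
    slide.  Reproducible for a fixed seed.
    """
    if sample_interval <= 0:
        raise ThermalError("sample_interval must be > 0")
    import warnings

    if sample_interval > model.time_constant / 10:
        warnings.warn(
            "sample_interval exceeds tau/10; discretization may be coarse",
            stacklevel=2,
        )
    n = int(round(duration / sample_interval)) + 1
    rng = np.random.default_rng(seed)
    alpha = 1.0 - math.exp(-sample_interval / model.time_constant)
    delay = int(round(model.dead_time / sample_interval))
    u_hist = deque([0.0] * delay, maxlen=delay or None)

    if slide_lag is not None:
        alpha_s = 1.0 - math.exp(-sample_interval / slide_lag.time_constant)
        s_delay = int(round(slide_lag.dead_time / sample_interval))
        s_hist = deque([model.ambient] * s_delay, maxlen=s_delay or None)
        slide = np.empty(n)
        T_s = model.ambient
    else:
        slide = None

    times = np.arange(n) * sample_interval
    sps = np.empty(n)
    plates = np.empty(n)
    outs = np.empty(n)

    T = model.ambient
    integ = 0.0
    prev_err = None
    for k in range(n):
        sp = float(setpoint_schedule(times[k]))
        reading = T + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        if calibration is not None:
            reading = calibration.apply(reading)
        err = sp - reading
        if prev_err is None:
            prev_err = err
        integ_new = integ + 0.5 * (err + prev_err) * sample_interval
        u_raw = pi_controller_output(err, integ_new, gains)
        if gains.derivative:
            u_raw += gains.derivative * (err - prev_err) / sample_interval
        prev_err = err
        if actuator is not None:
            saturated = u_raw < 0.0 or u_raw > actuator.full_scale
            u = actuator.quantize(u_raw)
            if not saturated:
                integ = integ_new
        else:
            u = u_raw
            integ = integ_new

        sps[k] = sp
        plates[k] = reading
        outs[k] = u
        if slide is not None:
            slide[k] = T_s

        if delay:
            u_eff = u_hist.popleft()
            u_hist.append(u)
        else:
            u_eff = u
        T = T + alpha * (model.ambient + model.gain * u_eff - T)
        if abs(T) > 500.0:
            raise RuntimeError(
                f"closed loop diverged (|T| > 500 degC) with gains "
                f"Kc={gains.proportional}, Ki={gains.integral}"
            )
        if slide is not None:
            if s_delay:
                src = s_hist.popleft()
                s_hist.append(T)
            else:
                src = T
            target = slide_lag.ambient + slide_lag.gain * (src - slide_lag.ambient)
            T_s = T_s + alpha_s * (target - T_s)

    return ClosedLoopTrace(times, sps, plates, outs, slide)


def step_metrics(trace: ClosedLoopTrace, settling_band: float = 0.02) -> StepMetrics:
    """Rise time (10-90%), settling time (entry into a +-band around the
    final setpoint) and percent overshoot of a single-step trace.

    All quantities are measured relative to the pre-step baseline and the
    step time, so the metrics are invariant to temperature offsets and
    time shifts of the trace.
    """
    sp = np.asarray(trace.setpoints, dtype=float)
    y = np.asarray(trace.plate_temperatures, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    changes = np.flatnonzero(np.diff(sp) != 0)
    if len(changes) == 0:
        raise ThermalError("setpoint never changes: not a step trace")
    if len(changes) > 1:
        raise ThermalError("trace contains more than one setpoint step")
    i0 = int(changes[0]) + 1
    t0 = t[i0]
    baseline = sp[i0 - 1]
    target = sp[-1]
    dsp = target - baseline
    if dsp == 0:
        raise ThermalError("zero-magnitude setpoint step")

    rel_t = t[i0:] - t0
    rel_y = (y[i0:] - baseline) / dsp  # normalized 0..1 response
    if rel_y.max() < 0.9:
        raise ThermalError("trace never reaches 90% of the step")
    t10 = _crossing_time(rel_t, rel_y, 0.10)
    t90 = _crossing_time(rel_t, rel_y, 0.90)
    rise = t90 - t10

    outside = np.abs(rel_y - 1.0) > settling_band
    if outside.any():
        last_out = int(np.flatnonzero(outside)[-1])
        if last_out == len(rel_y) - 1:
            raise ThermalError("trace does not settle within the band")
        settling = float(rel_t[last_out + 1])
    else:
        settling = float(rel_t[0])

    overshoot = max(0.0, 100.0 * (rel_y.max() - 1.0))
    return StepMetrics(rise_time=float(rise), settling_time=settling, overshoot=overshoot)


def fit_calibration(
    readings: Sequence[float], references: Sequence[float]
) -> CalibrationCorrection:
    """Ordinary least squares of reference on reading."""
    r = np.asarray(readings, dtype=float)
    ref = np.asarray(references, dtype=float)
    if r.shape != ref.shape or r.ndim != 1:
        raise ThermalError("readings and references must be equal-length 1-D")
    if len(r) < 3:
        raise ThermalError("need at least 3 paired calibration points")
    if np.ptp(r) == 0:
        raise ThermalError("degenerate design: all readings identical")
    slope, intercept = np.polyfit(r, ref, 1)
    return CalibrationCorrection(slope=float(slope), intercept=float(intercept))
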