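"""Rest-to-rest translation motion profiles for distance reproduction.

Two profile families are used in the task. The *target* translation follows a
raised-cosine velocity profile (sinusoidal acceleration), parameterised by the
distance to be traveled and a fixed duration. The *test* translation, identical
for every trial, accelerates along the first half of a sinusoid and then
decelerates at a constant rate until it halts; the observer presses a button
somewhere along it, and the position at the press time is the reproduced
distance.

All profiles start and end at rest and move unidirectionally along a straight
path; translation direction is a label attached elsewhere, never a signed
kinematic quantity here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotionProfile",
    "TestProfileParams",
    "target_profile",
    "solve_test_profile",
    "solve_test_profile_from_decel",
    "build_test_profile",
    "position_at",
    "round_half_up",
    "DEFAULT_SAMPLE_RATE",
    "TEST_PEAK_ACCEL",
    "TEST_TOTAL_TIME",
    "TEST_TOTAL_DISTANCE",
    "TARGET_DURATION",
]

#: default sampling rate (Hz); fine enough that printed 2-decimal kinematic
#: values are met after rounding
DEFAULT_SAMPLE_RATE = 1000.0

#: canonical test-translation parameters used throughout the study design
TEST_PEAK_ACCEL = 1.55  # m/s^2
TEST_TOTAL_TIME = 5.0  # s
TEST_TOTAL_DISTANCE = 2.5  # m
TARGET_DURATION = 3.0  # s


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention used when
    comparing against printed 2-decimal values)."""
    factor = 10.0**ndigits
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x) if x else 0.0


@dataclass(frozen=True)
class MotionProfile:
    """Sampled kinematics of one translation on a uniform time grid from 0.

    velocity is the integral of acceleration and position the integral of
    velocity (exact analytic forms are stored; the trapezoid-rule integrals of
    the sampled series agree within a tolerance that shrinks as
    1/sample_rate^2).
    """

    time: np.ndarray
    acceleration: np.ndarray
    velocity: np.ndarray
    position: np.ndarray
    sample_rate: float

    @property
    def duration(self) -> float:
        return float(self.time[-1])

    @property
    def total_distance(self) -> float:
        return float(self.position[-1])

    @property
    def peak_acceleration(self) -> float:
        return float(np.max(np.abs(self.acceleration)))

    def integration_residual(self) -> float:
        """Max deviation between the stored velocity and the trapezoid-rule
        integral of the stored acceleration (convergence diagnostic)."""
        from scipy.integrate import cumulative_trapezoid

        v_num = cumulative_trapezoid(self.acceleration, self.time, initial=0.0)
        return float(np.max(np.abs(v_num - self.velocity)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "acceleration": self.acceleration,
                "velocity": self.velocity,
                "position": self.position,
            }
        )

    def to_csv(self, path) -> None:
        """Export as CSV with mandatory header time,acceleration,velocity,position."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MotionProfile":
        df = pd.read_csv(path)
        t = df["time"].to_numpy(float)
        rate = (len(t) - 1) / t[-1] if t[-1] > 0 else DEFAULT_SAMPLE_RATE
        return cls(
            time=t,
            acceleration=df["acceleration"].to_numpy(float),
            velocity=df["velocity"].to_numpy(float),
            position=df["position"].to_numpy(float),
            sample_rate=rate,
        )


@dataclass(frozen=True)
class TestProfileParams:
    """Parameters of the half-sinusoid-then-constant-deceleration test profile.

    Rest-to-rest closure requires the peak velocity reached at the end of the
    acceleration phase, v1 = 2*A*t1/pi, to be exactly shed by the constant
    deceleration: v1 = d*(T - t1). Total distance S = A*t1^2/pi + v1*(T-t1)/2,
    which simplifies to S = A*t1*T/pi.
    """

    peak_accel: float  # A, m/s^2
    accel_phase_duration: float  # t1, s
    decel_magnitude: float  # d > 0, m/s^2
    total_time: float  # T, s
    total_distance: float  # S, m

    @property
    def peak_velocity(self) -> float:
        return 2.0 * self.peak_accel * self.accel_phase_duration / np.pi

    def closure_residuals(self) -> tuple[float, float]:
        """Residuals of the two rest-to-rest closure constraints."""
        v1 = self.peak_velocity
        r1 = v1 - self.decel_magnitude * (self.total_time - self.accel_phase_duration)
        r2 = (
            self.peak_accel * self.accel_phase_duration**2 / np.pi
            + v1 * (self.total_time - self.accel_phase_duration) / 2.0
            - self.total_distance
        )
        return float(r1), float(r2)

    def validate(self, tol: float = 1e-6) -> None:
        if not (0.0 < self.accel_phase_duration < self.total_time):
            raise ValueError("acceleration phase must lie strictly inside (0, T)")
        if self.decel_magnitude <= 0 or self.peak_accel <= 0:
            raise ValueError("peak acceleration and deceleration must be positive")
        r1, r2 = self.closure_residuals()
        if abs(r1) > tol or abs(r2) > tol:
            raise ValueError(
                f"parameters violate rest-to-rest closure (residuals {r1:.3g}, {r2:.3g})"
            )


def _check_rate(sample_rate: float, minimum: float = 50.0) -> None:
    if not np.isfinite(sample_rate) or sample_rate < minimum:
        raise ValueError(f"sample_rate must be ≥ {minimum} Hz")


def _time_grid(duration: float, sample_rate: float) -> np.ndarray:
    n = max(int(round(duration * sample_rate)), 1)
    return np.linspace(0.0, duration, n + 1)


def target_profile(
    distance: float, duration: float = TARGET_DURATION, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> MotionProfile:
    """Raised-cosine velocity profile covering `distance` in `duration`.

    v(t) = (D/T)*(1 - cos(2*pi*t/T)), a(t) = (2*pi*D/T^2)*sin(2*pi*t/T),
    x(t) = D*(t/T - sin(2*pi*t/T)/(2*pi)). Peak acceleration is 2*pi*D/T^2;
    in the study the duration is fixed at 3 s so the peak ranges from
    0.35 m/s^2 (D=0.5 m) to 1.05 m/s^2 (D=1.5 m).
    """
    if not np.isfinite(distance) or distance < 0:
        raise ValueError("distance must be finite and non-negative")
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError("duration must be finite and positive")
    _check_rate(sample_rate)
    t = _time_grid(duration, sample_rate)
    w = 2.0 * np.pi / duration
    acc = (2.0 * np.pi * distance / duration**2) * np.sin(w * t)
    vel = (distance / duration) * (1.0 - np.cos(w * t))
    pos = distance * (t / duration - np.sin(w * t) / (2.0 * np.pi))
    return MotionProfile(t, acc, vel, pos, sample_rate)


def solve_test_profile(
    peak_accel: float, total_time: float, total_distance: float
) -> TestProfileParams:
    """Solve the rest-to-rest closure for (t1, d) given (A, T, S).

    The closure equations collapse to S = A*t1*T/pi, giving t1 in closed form;
    d then follows from v1 = d*(T - t1).
    """
    A, T, S = peak_accel, total_time, total_distance
    if not all(np.isfinite([A, T, S])) or A <= 0 or T <= 0 or S <= 0:
        raise ValueError("peak_accel, total_time and total_distance must be positive")
    t1 = np.pi * S / (A * T)
    if not (0.0 < t1 < T):
        raise ValueError(
            f"no feasible rest-to-rest solution: required t1={t1:.4g} s not in (0, {T}) "
            "(distance too large for the given peak acceleration and time)"
        )
    v1 = 2.0 * A * t1 / np.pi
    d = v1 / (T - t1)
    return TestProfileParams(A, float(t1), float(d), T, S)


def solve_test_profile_from_decel(
    peak_accel: float, decel_magnitude: float, total_time: float
) -> TestProfileParams:
    """Solve the closure for (t1, S) given (A, d, T): t1 = pi*d*T/(2A + pi*d)."""
    A, d, T = peak_accel, decel_magnitude, total_time
    if not all(np.isfinite([A, d, T])) or A <= 0 or d <= 0 or T <= 0:
        raise ValueError("all parameters must be positive")
    t1 = np.pi * d * T / (2.0 * A + np.pi * d)
    S = A * t1 * T / np.pi
    return TestProfileParams(A, float(t1), d, T, float(S))


def build_test_profile(
    params: TestProfileParams, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> MotionProfile:
    """Sample the test translation: a(t) = A*sin(pi*t/t1) for t <= t1, then
    a(t) = -d until the halt at T."""
    params.validate()
    _check_rate(sample_rate)
    A, t1, d, T = (
        params.peak_accel,
        params.accel_phase_duration,
        params.decel_magnitude,
        params.total_time,
    )
    t = _time_grid(T, sample_rate)
    v1 = params.peak_velocity
    x1 = A * t1**2 / np.pi
    phase1 = t <= t1
    acc = np.where(phase1, A * np.sin(np.pi * t / t1), -d)
    vel = np.where(
        phase1,
        (A * t1 / np.pi) * (1.0 - np.cos(np.pi * t / t1)),
        v1 - d * (t - t1),
    )
    pos = np.where(
        phase1,
        (A * t1 / np.pi) * (t - (t1 / np.pi) * np.sin(np.pi * t / t1)),
        x1 + v1 * (t - t1) - 0.5 * d * (t - t1) ** 2,
    )
    # closure guarantees v(T)=0 analytically; clamp the last sample's tiny
    # floating-point remainder so position stays non-decreasing
    vel = np.maximum(vel, 0.0)
    return MotionProfile(t, acc, vel, pos, sample_rate)


def position_at(profile: MotionProfile, t) -> float | np.ndarray:
    """Position (m) at time t by linear interpolation of the position series.

    Maps a button-press time to a reproduced distance. t must lie within the
    profile's time span.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > profile.duration + 1e-12):
        raise ValueError(f"t must lie within [0, {profile.duration}] s")
    out = np.interp(t_arr, profile.time, profile.position)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
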