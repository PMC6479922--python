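"""Synthetic 6-axis IMU streams for scheduled range-of-motion exercises.

The simulator models each exercise as a single rotational degree of
freedom: the limb tilt angle about one sensor axis follows the schedule's
rest/ramp profile, the accelerometer reads unit gravity rotated into the
sensor frame, and the gyroscope reads the analytic time derivative of the
angle on the exercise's rotation axis.  Gaussian noise is added per
channel.  All randomness is driven by the config seed, so a fixed seed
reproduces streams bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .schedule import MotionSchedule, standard_schedule

Axis = Literal["x", "y", "z"]
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class ExerciseSpec:
    """An exercise schedule plus the sensor axes it plays out on.

    ``angle_axis`` is the axis whose tilt tracks the limb angle (the axis
    the angle feature is computed about); ``gyro_axis`` is the gyroscope
    component that registers the rotation rate.  They differ only for the
    pronation–supination exercise, where the wear orientation puts the
    forearm axis along the sensor's y axis.
    """

    schedule: MotionSchedule
    angle_axis: Axis = "x"
    gyro_axis: Axis = "x"

    @property
    def exercise_id(self) -> str:
        return self.schedule.exercise_id


_AXES: dict[str, tuple[Axis, Axis]] = {
    "A": ("x", "x"),
    "B": ("x", "x"),
    "C": ("x", "x"),
    "D": ("x", "y"),
    "E": ("z", "z"),
}


def exercise_spec(exercise_id: str, cycles: int = 5) -> ExerciseSpec:
    """Built-in spec for exercise ``A``–``E``."""
    angle_axis, gyro_axis = _AXES[exercise_id.upper()]
    return ExerciseSpec(standard_schedule(exercise_id, cycles), angle_axis, gyro_axis)


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling and noise settings.

    ``frequency`` must lie in the sensor's 20–100 Hz range.  Noise levels
    default to a plausible consumer-IMU scale: 0.02 g accelerometer noise
    and 1 deg/s gyroscope noise (standard deviations).
    """

    frequency: float = 100.0
    noise_sd_accel: float = 0.02
    noise_sd_gyro: float = 1.0
    seed: int = 0
    ramp_shape: Literal["linear", "smoothstep"] = "smoothstep"

    def __post_init__(self) -> None:
        if not 20.0 <= self.frequency <= 100.0:
            raise ValueError("frequency must lie in [20, 100] Hz")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.ramp_shape not in ("linear", "smoothstep"):
            raise ValueError(f"unknown ramp shape {self.ramp_shape!r}")


@dataclass
class ImuStream:
    """Timestamped 6-axis samples: accel in g, gyro in deg/s, sensor-local axes."""

    t: np.ndarray
    accel: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.t)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must have shape (n, 3)")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape != (n,):
                raise ValueError("labels must have shape (n,)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def frequency(self) -> float:
        """Mean sampling rate in Hz."""
        if len(self.t) < 2:
            raise ValueError("need at least two samples to infer a frequency")
        return float(1.0 / np.mean(np.diff(self.t)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "ax": self.accel[:, 0],
                "ay": self.accel[:, 1],
                "az": self.accel[:, 2],
                "gx": self.gyro[:, 0],
                "gy": self.gyro[:, 1],
                "gz": self.gyro[:, 2],
            }
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImuStream":
        labels = df["label"].to_numpy() if "label" in df.columns else None
        return cls(
            t=df["t"].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            labels=labels,
        )


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_deriv(u: np.ndarray) -> np.ndarray:
    return 6.0 * u * (1.0 - u)


def angle_trajectory(
    schedule: MotionSchedule, t: np.ndarray, ramp_shape: str = "smoothstep"
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless tilt angle (deg) and angular velocity (deg/s) at each time.

    Rest motions hold their angle with exactly zero velocity; ramps
    interpolate between the endpoint angles, either linearly or with a
    smoothstep (zero endpoint velocity).
    """
    t = np.asarray(t, dtype=float)
    idx = schedule.motion_index_at(t)
    tc = np.mod(t, schedule.cycle_duration)
    starts = np.concatenate([[0.0], np.cumsum([m.duration for m in schedule.motions])[:-1]])
    durs = np.array([m.duration for m in schedule.motions])
    a0 = np.array([m.start_angle for m in schedule.motions])[idx]
    a1 = np.array([m.end_angle for m in schedule.motions])[idx]
    dur = durs[idx]
    u = np.clip((tc - starts[idx]) / dur, 0.0, 1.0)
    if ramp_shape == "linear":
        s, ds = u, np.ones_like(u)
    else:
        s, ds = _smoothstep(u), _smoothstep_deriv(u)
    angle = a0 + (a1 - a0) * s
    velocity = (a1 - a0) * ds / dur
    is_rest = a0 == a1
    velocity = np.where(is_rest, 0.0, velocity)
    return angle, velocity


def _gravity_from_angle(angle_deg: np.ndarray, angle_axis: Axis) -> np.ndarray:
    """Unit gravity reaction vector in the sensor frame for a given tilt."""
    rad = np.deg2rad(angle_deg)
    n = len(angle_deg)
    a = np.zeros((n, 3))
    if angle_axis == "x":
        # gravity rotates in the sensor y-z plane; tilt_x = atan2(ay, az)
        a[:, 1] = np.sin(rad)
        a[:, 2] = np.cos(rad)
    elif angle_axis == "z":
        # gravity rotates in the sensor x-y plane; tilt_z = atan2(ay, ax)
        a[:, 0] = np.cos(rad)
        a[:, 1] = np.sin(rad)
    else:
        raise ValueError("angle_axis must be 'x' or 'z' (y-tilt cannot span a half turn)")
    return a


def simulate_exercise(
    spec: ExerciseSpec, cfg: SimulationConfig
) -> tuple[ImuStream, np.ndarray]:
    """Generate a labeled 6-axis stream for one scheduled exercise.

    Returns the stream and the ground-truth label series (midpoint labels,
    also attached to the stream).  The sample count is
    ``floor(total_duration * frequency)``.
    """
    schedule = spec.schedule
    n = int(math.floor(schedule.total_duration * cfg.frequency))
    t = np.arange(n) / cfg.frequency
    angle, velocity = angle_trajectory(schedule, t, cfg.ramp_shape)
    accel = _gravity_from_angle(angle, spec.angle_axis)
    gyro = np.zeros((n, 3))
    gyro[:, _AXIS_INDEX[spec.gyro_axis]] = velocity
    if cfg.noise_sd_accel > 0 or cfg.noise_sd_gyro > 0:
        rng = np.random.default_rng(cfg.seed)
        accel = accel + rng.normal(0.0, cfg.noise_sd_accel, size=accel.shape)
        gyro = gyro + rng.normal(0.0, cfg.noise_sd_gyro, size=gyro.shape)
    labels = schedule.label_stream(t, mode="midpoint")
    return ImuStream(t, accel, gyro, labels), labels


def inject_outliers(
    stream: ImuStream, fraction: float, magnitude: float = 500.0, seed: int = 0
) -> ImuStream:
    """Push a fraction of samples' gyro readings far outside any trained
    membership-function support, to exercise downstream outlier handling.

    Exactly ``floor(fraction * n)`` samples are perturbed by adding
    ``magnitude`` (deg/s) to every gyro component.  ``fraction`` 0 returns
    an identical copy; a fixed seed picks the same samples every time.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = len(stream)
    k = int(math.floor(fraction * n))
    gyro = stream.gyro.copy()
    if k > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=k, replace=False)
        gyro[idx] += magnitude
    return ImuStream(stream.t.copy(), stream.accel.copy(), gyro,
                     None if stream.labels is None else stream.labels.copy())
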