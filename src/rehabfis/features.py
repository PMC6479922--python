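"""From raw 6-axis streams to the candidate recognition features.

The features are the ones a gravity-referenced wristband can deliver at
slow rehabilitation speeds:

* ``rACC{x,y,z}`` — acceleration relative to the calibration origin (g);
  non-zero when the limb starts moving.
* ``rANGV{x,y,z}`` — bias-corrected angular velocity (deg/s); non-zero in
  movement.
* ``rANG{x,y,z}`` — tilt angles (degrees) derived from the gravity
  direction, unwrapped along time so a trajectory can sweep through ±180°
  without wraparound jumps; they encode limb position.

Tilt convention: ``rANGx = atan2(ay, az)``, ``rANGy = atan2(-ax,
hypot(ay, az))`` and ``rANGz = atan2(ay, ax)`` (the z tilt reads the
gravity direction projected on the sensor's x-y plane, which is the
observable quantity for motions performed with the z axis horizontal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import fft as _fft
from sklearn.base import BaseEstimator, TransformerMixin

from .schedule import VIRTUAL_SENTINEL, MotionSchedule
from .simulate import ImuStream

FEATURE_COLUMNS = [
    "rACCx", "rACCy", "rACCz",
    "rANGVx", "rANGVy", "rANGVz",
    "rANGx", "rANGy", "rANGz",
]


@dataclass(frozen=True)
class Origin:
    """Calibration reference taken over the initial rest window."""

    accel_mean: np.ndarray
    gyro_bias: np.ndarray
    tilt: np.ndarray  # degrees, per axis


def tilt_angles(accel: np.ndarray) -> np.ndarray:
    """Tilt angles (degrees, in (-180, 180]) from an acceleration vector.

    Accepts a single 3-vector or an (n, 3) array.  Rejects (near-)zero
    vectors: a free-falling or unpowered sensor carries no gravity
    reference, so no tilt is defined.
    """
    a = np.asarray(accel, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    norms = np.linalg.norm(a, axis=1)
    if np.any(norms < 1e-6):
        raise ValueError("zero-magnitude acceleration: tilt undefined (free fall?)")
    ax, ay, az = a[:, 0], a[:, 1], a[:, 2]
    tx = np.degrees(np.arctan2(ay, az))
    ty = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
    tz = np.degrees(np.arctan2(ay, ax))
    out = np.column_stack([tx, ty, tz])
    return out[0] if single else out


def calibrate_origin(stream: ImuStream, window: float = 0.5) -> Origin:
    """Per-axis means over the initial ``window`` seconds.

    The subject holds the initial posture at the start of the schedule, so
    the window mean estimates the resting gravity direction and the gyro
    bias.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t0 = stream.t[0]
    if stream.t[-1] - t0 < window:
        raise ValueError(f"stream shorter than the {window} s calibration window")
    sel = stream.t <= t0 + window
    accel_mean = stream.accel[sel].mean(axis=0)
    gyro_bias = stream.gyro[sel].mean(axis=0)
    return Origin(accel_mean, gyro_bias, tilt_angles(accel_mean))


def _canonical_unwrap(tilt_deg: np.ndarray) -> np.ndarray:
    """Unwrap a tilt series along time and shift it by whole revolutions so
    its midrange lands in (-180, 180]."""
    unwrapped = np.unwrap(tilt_deg, period=360.0)
    mid = 0.5 * (unwrapped.min() + unwrapped.max())
    shift = 360.0 * np.ceil((mid - 180.0) / 360.0)
    return unwrapped - shift


def relative_features(
    stream: ImuStream, origin: Origin, subtract_origin: bool = False
) -> pd.DataFrame:
    """Derive the relative feature table from a raw stream.

    ``rACC`` and ``rANGV`` are referenced to the calibration origin
    (acceleration offset and gyro bias removed).  ``rANG`` is the
    unwrapped tilt in the body-neutral reference, where holding the arm
    overhead reads ≈ 0° and hanging down reads ≈ -180°; pass
    ``subtract_origin=True`` to re-reference angles to the calibration
    instant instead.
    """
    racc = stream.accel - origin.accel_mean
    rangv = stream.gyro - origin.gyro_bias
    tilt = tilt_angles(stream.accel)
    rang = np.column_stack([_canonical_unwrap(tilt[:, i]) for i in range(3)])
    if subtract_origin:
        rang = rang - origin.tilt
    df = pd.DataFrame(
        np.column_stack([stream.t, racc, rangv, rang]),
        columns=["t"] + FEATURE_COLUMNS,
    )
    if stream.labels is not None:
        df["label"] = stream.labels
    return df


def label_stream(
    schedule: MotionSchedule,
    t: Sequence[float] | np.ndarray,
    mode: str = "midpoint",
    seed: Optional[int] = None,
) -> np.ndarray:
    """Assign numeric labels to timestamps (see ``MotionSchedule.label_stream``)."""
    return schedule.label_stream(np.asarray(t, dtype=float), mode=mode, seed=seed)


def decode_label(label: float, schedule: MotionSchedule) -> Optional[str]:
    """Motion name for a crisp label; ``"virtual"`` or ``None`` when outside."""
    return schedule.decode_label(label)


def merge_complex(
    datasets: Sequence[pd.DataFrame],
    used_features: Sequence[Sequence[str]],
    sentinel: float = VIRTUAL_SENTINEL,
) -> pd.DataFrame:
    """Merge labeled sub-exercise feature tables into one training table.

    A complex exercise trains a single fuzzy system over the union of its
    sub-exercises' features, which must be pairwise disjoint — the same
    feature cannot drive different motions in one rule base.  Features a
    row's sub-exercise does not use are filled with the virtual sentinel
    so training can mask them out.
    """
    if len(datasets) != len(used_features):
        raise ValueError("need one used-feature list per dataset")
    sets = [set(f) for f in used_features]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            common = sets[i] & sets[j]
            if common:
                raise ValueError(
                    "sub-exercises of a complex exercise may not share features "
                    f"(datasets {i} and {j} both use {sorted(common)}); identical "
                    "features confuse a single rule base"
                )
    all_features = [f for fs in used_features for f in fs]
    parts = []
    for df, feats in zip(datasets, used_features):
        missing = [f for f in feats if f not in df.columns]
        if missing:
            raise ValueError(f"dataset lacks its own used features {missing}")
        part = pd.DataFrame({"t": df["t"].to_numpy()})
        for f in all_features:
            part[f] = df[f].to_numpy() if f in feats else sentinel
        if "label" in df.columns:
            part["label"] = df["label"].to_numpy()
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def spectrum(series: Sequence[float] | np.ndarray, frequency: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided discrete-Fourier magnitude spectrum of a feature series.

    Returns the non-negative frequency bins (Hz) and ``|X_k|`` from the
    unnormalized DFT, for inspecting which motion periodicities a feature
    carries before choosing membership functions.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    X = _fft.rfft(x)
    freqs = _fft.rfftfreq(x.size, d=1.0 / frequency)
    return freqs, np.abs(X)


class ImuFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: raw stream rows → relative feature matrix.

    ``fit`` calibrates the origin on the initial rest window of the input;
    ``transform`` produces the nine relative features (columns in the order
    of :data:`FEATURE_COLUMNS`).  Input ``X`` is an (n, 7) array with
    columns ``t, ax, ay, az, gx, gy, gz`` (or a matching DataFrame).
    """

    def __init__(self, window: float = 0.5, subtract_origin: bool = False):
        self.window = window
        self.subtract_origin = subtract_origin

    @staticmethod
    def _to_stream(X) -> ImuStream:
        if isinstance(X, pd.DataFrame):
            return ImuStream.from_frame(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 7:
            raise ValueError("expected columns t, ax, ay, az, gx, gy, gz")
        return ImuStream(X[:, 0], X[:, 1:4], X[:, 4:7])

    def fit(self, X, y=None):
        stream = self._to_stream(X)
        self.origin_ = calibrate_origin(stream, window=self.window)
        self.n_features_in_ = 7
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "origin_"):
            raise AttributeError("ImuFeatureExtractor is not fitted yet")
        stream = self._to_stream(X)
        df = relative_features(stream, self.origin_, subtract_origin=self.subtract_origin)
        return df[FEATURE_COLUMNS].to_numpy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_COLUMNS, dtype=object)
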