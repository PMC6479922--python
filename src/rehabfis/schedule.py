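"""Scheduled range-of-motion exercises and their motion-label arithmetic.

A rehabilitation exercise is a fixed, cyclic schedule of motions (rest →
move → rest → move).  Each motion owns a half-open real label range
``[a, b)``; any number inside the range identifies the motion, so a
regression model can be trained on arbitrary in-range targets and its
crisp output decoded back to a motion name.  Labels in ``[-0.5, 0)`` are
reserved for *virtual* motions — placeholder consequents that complete a
fuzzy rule grid but never correspond to real movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

#: label range reserved for virtual (dummy-rule) motions
VIRTUAL_RANGE: tuple[float, float] = (-0.5, 0.0)

#: sentinel stored in place of a feature a sub-exercise does not use
VIRTUAL_SENTINEL: float = -999.0

LabelMode = Literal["midpoint", "ramp", "uniform"]


@dataclass(frozen=True)
class Motion:
    """One step of an exercise schedule.

    Parameters
    ----------
    name:
        Motion name, e.g. ``"flex"``.
    duration:
        Step duration in seconds (> 0).
    label_range:
        Half-open label interval ``[a, b)`` identifying the motion.
    profile:
        ``"rest"`` (hold a posture) or ``"ramp"`` (move between postures).
    start_angle, end_angle:
        Limb tilt angle (degrees) about the exercise's primary axis at the
        start and end of the step; equal for a rest.
    """

    name: str
    duration: float
    label_range: tuple[float, float]
    profile: Literal["rest", "ramp"]
    start_angle: float
    end_angle: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"motion {self.name!r}: duration must be > 0")
        a, b = self.label_range
        if not a < b:
            raise ValueError(f"motion {self.name!r}: empty label range {self.label_range}")
        if self.profile == "rest" and self.start_angle != self.end_angle:
            raise ValueError(f"motion {self.name!r}: rest must hold a constant angle")
        if self.profile not in ("rest", "ramp"):
            raise ValueError(f"motion {self.name!r}: unknown profile {self.profile!r}")

    @property
    def label_midpoint(self) -> float:
        a, b = self.label_range
        return 0.5 * (a + b)


@dataclass(frozen=True)
class MotionSchedule:
    """Ordered motions of one exercise, repeated ``cycles`` times."""

    exercise_id: str
    motions: tuple[Motion, ...]
    cycles: int = 5

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be a positive integer")
        if len(self.motions) < 1:
            raise ValueError("schedule needs at least one motion")
        ranges = sorted(m.label_range for m in self.motions)
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping label ranges [{a1},{b1}) and [{a2},{b2})")
        for m in self.motions:
            a, b = m.label_range
            if a < VIRTUAL_RANGE[1] and b > VIRTUAL_RANGE[0]:
                raise ValueError(f"motion {m.name!r} label range intrudes on the virtual range")

    @property
    def cycle_duration(self) -> float:
        return float(sum(m.duration for m in self.motions))

    @property
    def total_duration(self) -> float:
        return self.cycle_duration * self.cycles

    @property
    def motion_names(self) -> list[str]:
        return [m.name for m in self.motions]

    def motion_index_at(self, t: np.ndarray | float) -> np.ndarray:
        """Index (into ``motions``) of the scheduled motion at each time.

        Times must lie in ``[0, total_duration)`` (the exact end instant is
        folded onto the last motion).
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.total_duration):
            raise ValueError("timestamp outside the scheduled duration")
        tc = np.mod(t, self.cycle_duration)
        # end instant of the last cycle folds to 0; map it back to the end
        tc = np.where((t > 0) & (tc == 0) & (t >= self.total_duration), self.cycle_duration, tc)
        edges = np.cumsum([m.duration for m in self.motions])
        idx = np.searchsorted(edges, tc, side="right")
        return np.minimum(idx, len(self.motions) - 1)

    def motion_at(self, t: float) -> Motion:
        return self.motions[int(self.motion_index_at(float(t)))]

    # ------------------------------------------------------------------
    # labels
    # ------------------------------------------------------------------
    def label_stream(
        self,
        t: Sequence[float] | np.ndarray,
        mode: LabelMode = "midpoint",
        seed: Optional[int] = None,
    ) -> np.ndarray:
        """Assign a numeric motion label to each timestamp.

        ``midpoint`` places every label at the centre of its motion's range,
        ``ramp`` sweeps the range linearly over the motion's duration, and
        ``uniform`` draws i.i.d. labels from the range (seeded).
        """
        t = np.asarray(t, dtype=float)
        idx = self.motion_index_at(t)
        lo = np.array([m.label_range[0] for m in self.motions])[idx]
        hi = np.array([m.label_range[1] for m in self.motions])[idx]
        if mode == "midpoint":
            return 0.5 * (lo + hi)
        if mode == "ramp":
            tc = np.mod(t, self.cycle_duration)
            starts = np.concatenate([[0.0], np.cumsum([m.duration for m in self.motions])[:-1]])
            durs = np.array([m.duration for m in self.motions])
            frac = (tc - starts[idx]) / durs[idx]
            lab = lo + frac * (hi - lo)
            return np.minimum(lab, np.nextafter(hi, -np.inf))
        if mode == "uniform":
            rng = np.random.default_rng(seed)
            return rng.uniform(lo, hi)
        raise ValueError(f"unknown label mode {mode!r}")

    def decode_label(self, label: float) -> Optional[str]:
        """Map a crisp label back to a motion name.

        Returns ``"virtual"`` for labels inside the reserved virtual range
        and ``None`` for labels outside every range (including NaN, which
        marks an outlier with no inferred label).
        """
        if label is None or (isinstance(label, float) and np.isnan(label)):
            return None
        if VIRTUAL_RANGE[0] <= label < VIRTUAL_RANGE[1]:
            return "virtual"
        for m in self.motions:
            a, b = m.label_range
            if a <= label < b:
                return m.name
        return None

    def decode_labels(self, labels: Iterable[float]) -> list[Optional[str]]:
        return [self.decode_label(float(v)) for v in labels]

    def neighbors(self, motion_name: str) -> tuple[str, str]:
        """Temporally adjacent motions (previous, next), cyclic."""
        names = self.motion_names
        i = names.index(motion_name)
        return names[i - 1], names[(i + 1) % len(names)]


def _sched(exercise_id: str, spec: list[tuple[str, float, tuple[float, float], float, float]],
           cycles: int) -> MotionSchedule:
    motions = []
    for name, dur, rng, a0, a1 in spec:
        motions.append(Motion(name, dur, rng, "rest" if a0 == a1 else "ramp", a0, a1))
    return MotionSchedule(exercise_id, tuple(motions), cycles)


# Label ranges follow the published exercise design; the temporal order within a
# cycle is rest → move → rest → move.  Note the pronation–supination exercise
# keeps its printed ranges, which skip [14, 15).
_STANDARD: dict[str, list[tuple[str, float, tuple[float, float], float, float]]] = {
    # shoulder flexion-extension: arm hangs down (-180°), sweeps to overhead/neutral (0°)
    "A": [
        ("rest_down", 2.0, (0.0, 1.0), -180.0, -180.0),
        ("flex", 4.0, (3.0, 4.0), -180.0, 0.0),
        ("rest_up", 2.0, (2.0, 3.0), 0.0, 0.0),
        ("ext", 4.0, (1.0, 2.0), 0.0, -180.0),
    ],
    # shoulder horizontal abduction-adduction: arm down (-180°) to shoulder level (-90°)
    "B": [
        ("rest_low", 2.0, (4.0, 5.0), -180.0, -180.0),
        ("abd", 4.0, (5.0, 6.0), -180.0, -90.0),
        ("rest_half", 2.0, (6.0, 7.0), -90.0, -90.0),
        ("add", 4.0, (7.0, 8.0), -90.0, -180.0),
    ],
    # elbow external-internal rotation: forearm sweeps a quarter turn
    "C": [
        ("rest_inside", 2.0, (8.0, 9.0), -90.0, -90.0),
        ("er", 4.0, (9.0, 10.0), -90.0, 0.0),
        ("rest_outside", 2.0, (10.0, 11.0), 0.0, 0.0),
        ("ir", 4.0, (11.0, 12.0), 0.0, -90.0),
    ],
    # forearm pronation-supination: palm up (0°) to palm down (-180°)
    "D": [
        ("rest_on", 2.0, (12.0, 13.0), 0.0, 0.0),
        ("pron", 4.0, (13.0, 14.0), 0.0, -180.0),
        ("rest_under", 2.0, (15.0, 16.0), -180.0, -180.0),
        ("supin", 4.0, (16.0, 17.0), -180.0, 0.0),
    ],
    # wrist ulnar-radial deviation: ±30° swing in the desk plane
    "E": [
        ("rest_right", 2.0, (17.0, 18.0), -30.0, -30.0),
        ("ulnar_dev", 4.0, (18.0, 19.0), -30.0, 30.0),
        ("rest_left", 2.0, (19.0, 20.0), 30.0, 30.0),
        ("rad_dev", 4.0, (20.0, 21.0), 30.0, -30.0),
    ],
}

#: input features consumed per exercise (angular-velocity feature, angle feature)
EXERCISE_FEATURES: dict[str, tuple[str, str]] = {
    "A": ("rANGVx", "rANGx"),
    "B": ("rANGVx", "rANGx"),
    "C": ("rANGVx", "rANGx"),
    "D": ("rANGVy", "rANGx"),
    "E": ("rANGVz", "rANGz"),
}


def standard_schedule(exercise_id: str, cycles: int = 5) -> MotionSchedule:
    """The built-in schedule for exercise ``A``–``E`` (12 s cycle, 5 cycles)."""
    try:
        spec = _STANDARD[exercise_id.upper()]
    except KeyError:
        raise ValueError(f"unknown exercise {exercise_id!r}; expected one of A-E") from None
    return _sched(exercise_id.upper(), spec, cycles)


def schedule_to_dict(schedule: MotionSchedule) -> dict:
    return {
        "exercise_id": schedule.exercise_id,
        "cycles": schedule.cycles,
        "motions": [
            {
                "name": m.name,
                "duration": m.duration,
                "label_range": list(m.label_range),
                "profile": m.profile,
                "start_angle": m.start_angle,
                "end_angle": m.end_angle,
            }
            for m in schedule.motions
        ],
    }


def schedule_from_dict(d: dict) -> MotionSchedule:
    motions = tuple(
        Motion(
            name=m["name"],
            duration=float(m["duration"]),
            label_range=(float(m["label_range"][0]), float(m["label_range"][1])),
            profile=m["profile"],
            start_angle=float(m["start_angle"]),
            end_angle=float(m["end_angle"]),
        )
        for m in d["motions"]
    )
    return MotionSchedule(d["exercise_id"], motions, int(d.get("cycles", 5)))
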