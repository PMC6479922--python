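"""Run trained-FIS inference and score it with the published schemes.

Three complementary views of recognition quality:

* **Adaptable scheme** — per-sample accuracy with a tolerance at motion
  changes: inside the first/last 10% of a scheduled segment, decoding to
  the temporally adjacent motion (cyclic across the cycle boundary) also
  counts as correct.
* **Quartile scheme** — each scheduled segment is cut at its 25/50/75%
  time positions; the first quarter, central half and last quarter are
  scored strictly.  The central half is the confidence interval: motion
  changes live in the outer quarters.
* **Confusion scheme** — per-second decisions (median label over the
  middle 50% of each second) are tallied as TP/FN/FP/TN against a target
  exercise, yielding sensitivity/fall-out/specificity/accuracy.

Outlier samples (no inferred label) count as errors everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fuzzy import FuzzySystem, sugeno_infer
from .schedule import MotionSchedule


def recognize(fis: FuzzySystem, features: pd.DataFrame, schedule: MotionSchedule) -> pd.DataFrame:
    """Infer per-sample motion labels and decode them.

    Returns a frame with columns ``t``, ``label`` (NaN marks an outlier),
    ``motion`` (decoded name, ``"virtual"`` or None) and ``scheduled``
    (ground-truth motion from the schedule).  The feature columns named in
    the system's metadata must be present.
    """
    names = fis.metadata.get("feature_names", fis.feature_names)
    missing = [f for f in names if f not in features.columns]
    if missing:
        raise KeyError(f"feature columns required by the FIS are missing: {missing}")
    t = features["t"].to_numpy(dtype=float)
    if t.size == 0:
        return pd.DataFrame(columns=["t", "label", "motion", "scheduled"])
    X = features[list(names)].to_numpy(dtype=float)
    labels = np.atleast_1d(sugeno_infer(fis, X))
    decoded = [schedule.decode_label(v) for v in labels]
    sched_idx = schedule.motion_index_at(t)
    scheduled = [schedule.motions[i].name for i in sched_idx]
    return pd.DataFrame({"t": t, "label": labels, "motion": decoded, "scheduled": scheduled})


def middle_of_second(series: pd.DataFrame, schedule: Optional[MotionSchedule] = None) -> pd.DataFrame:
    """Condense a recognition series to one decision per second.

    The decision for second ``k`` is the median inferred label over the
    central 50% of the samples with ``t`` in ``[k, k+1)``; outlier samples
    are dropped from the median, and a window whose central section is all
    outliers yields an outlier (NaN) decision.  The scheduled motion of a
    window is the modal scheduled motion of its central section.
    """
    if series.empty:
        return pd.DataFrame(columns=["t", "label", "motion", "scheduled"])
    t = series["t"].to_numpy(dtype=float)
    seconds = np.floor(t).astype(int)
    rows = []
    for k in np.unique(seconds):
        win = series.loc[seconds == k]
        n = len(win)
        central = win.iloc[n // 4 : n - n // 4] if n >= 4 else win
        vals = central["label"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        label = float(np.median(vals)) if vals.size else np.nan
        sched = central["scheduled"].mode().iloc[0] if "scheduled" in central else None
        motion = schedule.decode_label(label) if schedule is not None else None
        rows.append({"t": k + 0.5, "label": label, "motion": motion, "scheduled": sched})
    return pd.DataFrame(rows)


def _segment_positions(scheduled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each sample: fractional position in its contiguous scheduled
    segment, and the segment id."""
    n = len(scheduled)
    seg_id = np.zeros(n, dtype=int)
    for i in range(1, n):
        seg_id[i] = seg_id[i - 1] + (scheduled[i] != scheduled[i - 1])
    pos = np.empty(n)
    for s in np.unique(seg_id):
        idx = np.flatnonzero(seg_id == s)
        m = len(idx)
        pos[idx] = (np.arange(m) + 0.5) / m
    return pos, seg_id


def strict_rate(series: pd.DataFrame) -> dict[str, float]:
    """Fraction of samples whose decoded motion equals the scheduled one,
    per motion, plus the motion-averaged ``"average"``."""
    correct = series["motion"].to_numpy(dtype=object) == series["scheduled"].to_numpy(dtype=object)
    out: dict[str, float] = {}
    for name in pd.unique(series["scheduled"]):
        sel = series["scheduled"] == name
        out[name] = float(np.mean(correct[sel.to_numpy()]))
    out["average"] = float(np.mean([v for k, v in out.items() if k != "average"]))
    return out


def adaptable_rate(
    series: pd.DataFrame, schedule: MotionSchedule, boundary_fraction: float = 0.10
) -> dict[str, float]:
    """Recognition rate with motion-change tolerance.

    A sample is correct if it decodes to its scheduled motion, or if it
    lies within the first ``boundary_fraction`` of its segment and decodes
    to the previous motion (or the last fraction and the next motion),
    adjacency being cyclic across the cycle boundary.  Outliers are always
    incorrect.  Returns per-motion rates and their ``"average"``.
    """
    if series.empty:
        return {"average": float("nan")}
    scheduled = series["scheduled"].to_numpy(dtype=object)
    decoded = series["motion"].to_numpy(dtype=object)
    pos, _ = _segment_positions(scheduled)
    correct = decoded == scheduled
    for i in range(len(series)):
        if correct[i]:
            continue
        prev_m, next_m = schedule.neighbors(scheduled[i])
        if pos[i] < boundary_fraction and decoded[i] == prev_m:
            correct[i] = True
        elif pos[i] > 1.0 - boundary_fraction and decoded[i] == next_m:
            correct[i] = True
    out: dict[str, float] = {}
    for m in schedule.motions:
        sel = scheduled == m.name
        if np.any(sel):
            out[m.name] = float(np.mean(correct[sel]))
    out["average"] = float(np.mean([v for k, v in out.items() if k != "average"]))
    return out


def quartile_rates(series: pd.DataFrame, schedule: MotionSchedule) -> dict[str, dict[int, float]]:
    """Strict recognition rates over each segment's quartile sets.

    Per scheduled segment the time-ordered samples are cut at the 25/50/75%
    positions; the ``25`` set is the first quarter, ``50`` the central
    half, ``75`` the last quarter.  Rates are pooled over all segments of
    the same motion; segments with fewer than 4 samples are skipped with a
    warning.  Returns ``{motion: {25: r, 50: r, 75: r}}`` plus an
    ``"average"`` entry across motions.
    """
    scheduled = series["scheduled"].to_numpy(dtype=object)
    decoded = series["motion"].to_numpy(dtype=object)
    correct = decoded == scheduled
    _, seg_id = _segment_positions(scheduled)
    hits: dict[str, dict[int, list[bool]]] = {}
    for s in np.unique(seg_id):
        idx = np.flatnonzero(seg_id == s)
        n = len(idx)
        name = scheduled[idx[0]]
        if n < 4:
            warnings.warn(f"segment of motion {name!r} has only {n} samples; skipped")
            continue
        q1, q3 = n // 4, n - n // 4
        sets = {25: idx[:q1], 50: idx[q1:q3], 75: idx[q3:]}
        bucket = hits.setdefault(name, {25: [], 50: [], 75: []})
        for key, ids in sets.items():
            bucket[key].extend(correct[ids].tolist())
    out: dict[str, dict[int, float]] = {}
    for name, bucket in hits.items():
        out[name] = {k: float(np.mean(v)) for k, v in bucket.items()}
    if out:
        out["average"] = {
            k: float(np.mean([rates[k] for name, rates in out.items() if name != "average"]))
            for k in (25, 50, 75)
        }
    return out


def grade(rate: float) -> tuple[int, bool]:
    """Five-grade criterion for a recognition rate.

    Level 1: rate ≥ 0.8; level 2: [0.6, 0.8); level 3: [0.4, 0.6);
    level 4: [0.2, 0.4); level 0: below 0.2 (failed).  The motion is
    confirmed (accepted) when the rate exceeds 0.4.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate >= 0.8:
        level = 1
    elif rate >= 0.6:
        level = 2
    elif rate >= 0.4:
        level = 3
    elif rate >= 0.2:
        level = 4
    else:
        level = 0
    return level, rate > 0.4


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN tallies for one target exercise."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(
    decisions: pd.DataFrame,
    schedule: MotionSchedule,
    exercise_ranges: Sequence[tuple[float, float]],
    require_correct_motion: bool = True,
) -> ConfusionCounts:
    """Tally per-decision TP/FN/FP/TN against one target exercise.

    A decision is *positive* when its scheduled motion belongs to the
    target exercise's label ranges.  It is *predicted positive* when its
    inferred label falls inside those ranges and (by default) decodes to
    the scheduled motion; pass ``require_correct_motion=False`` to accept
    any in-exercise label.  Outlier decisions count against the system:
    FN when scheduled positive, FP otherwise, so the four counts always
    partition the decisions.
    """
    ranges = [(float(a), float(b)) for a, b in exercise_ranges]

    def in_ranges(v: float) -> bool:
        return any(a <= v < b for a, b in ranges)

    range_of = {m.name: m.label_range for m in schedule.motions}
    tp = fn = fp = tn = 0
    for _, row in decisions.iterrows():
        sched = row["scheduled"]
        a, b = range_of[sched]
        positive = in_ranges(0.5 * (a + b))
        label = row["label"]
        if isinstance(label, float) and np.isnan(label):
            if positive:
                fn += 1
            else:
                fp += 1
            continue
        pred_positive = in_ranges(float(label))
        if positive and pred_positive and require_correct_motion:
            pred_positive = schedule.decode_label(float(label)) == sched
        if positive:
            tp += pred_positive
            fn += not pred_positive
        else:
            fp += pred_positive
            tn += not pred_positive
    return ConfusionCounts(tp, fn, fp, tn)


def rates(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Sensitivity (TPR), fall-out (FPR), specificity (TNR) and accuracy.

    ``TPR = TP/(TP+FN)``, ``FPR = FP/(FP+TN)``, ``TNR = TN/(FP+TN)``,
    ``ACC = (TP+TN)/total``.  A rate whose denominator is zero is
    reported as None (absent), never as 0.
    """

    def div(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "TPR": div(c.tp, c.tp + c.fn),
        "FPR": div(c.fp, c.fp + c.tn),
        "TNR": div(c.tn, c.fp + c.tn),
        "ACC": div(c.tp + c.tn, c.total),
    }
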