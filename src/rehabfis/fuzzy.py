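"""Membership functions, Mamdani/Sugeno inference, and rule-grid tooling.

A :class:`FuzzySystem` holds input variables (each a list of membership
functions over a real range), a rule base, and either output membership
functions (Mamdani) or crisp consequents (Sugeno).  Inference follows the
classical recipes: rule firing strengths are the t-norm of antecedent
memberships; a Mamdani system clips each rule's output MF at its firing
strength, aggregates by max and takes the discrete centroid, while a
Sugeno system returns the firing-strength-weighted average of its crisp
consequents.  A sample whose inputs fall outside every membership support
fires no rule; it is flagged as an outlier (NaN output) rather than
raising, because out-of-range motion is an expected condition in
practice.
"""

from __future__ import annotations

import copy
import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import VIRTUAL_RANGE, VIRTUAL_SENTINEL, MotionSchedule

MF_SHAPES = ("triangle", "trapezoid", "gaussian", "bell", "sigmoid", "s", "z", "pi")

_PARAM_COUNT = {
    "triangle": 3,
    "trapezoid": 4,
    "gaussian": 2,
    "bell": 3,
    "sigmoid": 2,
    "s": 2,
    "z": 2,
    "pi": 4,
}

_ORDERED = {"triangle", "trapezoid", "s", "z", "pi"}

#: total-firing threshold below which a sample counts as an outlier
ZERO_FIRING_EPS = 1e-12


@dataclass
class MembershipFunction:
    """A named membership function of one of the standard shapes.

    Triangle params ``[a, b, c]`` are the left foot, apex and right foot;
    trapezoid params ``[a, b, c, d]`` the feet and shoulders; gaussian
    ``[mean, sigma]``; generalized bell ``[width, slope, center]``;
    sigmoid ``[slope, center]``; s/z ``[foot, shoulder]``; pi
    ``[a, b, c, d]`` (s-shape rising over [a, b], z-shape falling over
    [c, d]).  Malformed parameters are rejected at construction.
    """

    shape: str
    params: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in MF_SHAPES:
            raise ValueError(f"unknown membership shape {self.shape!r}")
        self.params = tuple(float(p) for p in self.params)
        if len(self.params) != _PARAM_COUNT[self.shape]:
            raise ValueError(
                f"{self.shape} needs {_PARAM_COUNT[self.shape]} params, got {len(self.params)}"
            )
        if not all(math.isfinite(p) for p in self.params):
            raise ValueError(f"non-finite parameters in {self.name or self.shape}")
        if self.shape in _ORDERED and list(self.params) != sorted(self.params):
            raise ValueError(
                f"{self.shape} {self.name!r}: params must be non-decreasing, got {self.params}"
            )
        if self.shape == "gaussian" and self.params[1] <= 0:
            raise ValueError("gaussian sigma must be positive")
        if self.shape == "bell" and self.params[0] <= 0:
            raise ValueError("bell width must be positive")

    # ------------------------------------------------------------------
    def __call__(self, x) -> np.ndarray:
        return mf_eval(self, x)

    def support(self) -> tuple[float, float]:
        """Interval outside which the MF is (numerically) zero."""
        p = self.params
        if self.shape in ("triangle", "s", "z", "pi", "trapezoid"):
            if self.shape == "s":
                return p[0], math.inf
            if self.shape == "z":
                return -math.inf, p[1]
            return p[0], p[-1]
        if self.shape == "gaussian":
            m, s = p
            return m - 8.0 * s, m + 8.0 * s
        return -math.inf, math.inf

    def centroid(self, resolution: int = 10001) -> float:
        """Area centroid of the MF curve (analytic for the piecewise-linear
        shapes, numeric otherwise)."""
        p = self.params
        if self.shape == "triangle":
            return (p[0] + p[1] + p[2]) / 3.0
        if self.shape == "trapezoid":
            a, b, c, d = p
            # centroid of a trapezoid with feet a,d and shoulders b,c
            num = (c**2 + d**2 + c * d) - (a**2 + b**2 + a * b)
            den = 3.0 * ((c + d) - (a + b))
            if den == 0:  # degenerate: a==b==c==d
                return 0.25 * (a + b + c + d)
            return num / den
        if self.shape == "gaussian":
            return p[0]
        lo, hi = self.support()
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"cannot take the centroid of unbounded shape {self.shape!r}")
        xs = np.linspace(lo, hi, resolution)
        mu = mf_eval(self, xs)
        area = np.trapezoid(mu, xs)
        if area <= 0:
            raise ValueError("zero-area membership function")
        return float(np.trapezoid(mu * xs, xs) / area)


def _lin_up(x, a, b):
    """Rising edge from (a, 0) to (b, 1); a step when a == b."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b > a, (x - a) / (b - a + (b == a)), (x >= a).astype(float))
    return np.clip(out, 0.0, 1.0)


def mf_eval(mf: MembershipFunction, x) -> np.ndarray:
    """Evaluate a membership function; always in [0, 1]."""
    x = np.asarray(x, dtype=float)
    p = mf.params
    if mf.shape == "triangle":
        a, b, c = p
        return np.minimum(_lin_up(x, a, b), 1.0 - _lin_up(x, b, c))
    if mf.shape == "trapezoid":
        a, b, c, d = p
        return np.minimum(_lin_up(x, a, b), 1.0 - _lin_up(x, c, d))
    if mf.shape == "gaussian":
        m, s = p
        return np.exp(-0.5 * ((x - m) / s) ** 2)
    if mf.shape == "bell":
        a, b, c = p
        return 1.0 / (1.0 + np.abs((x - c) / a) ** (2.0 * b))
    if mf.shape == "sigmoid":
        from scipy.special import expit

        a, c = p
        return expit(a * (x - c))
    if mf.shape == "s":
        a, b = p
        u = _lin_up(x, a, b)
        return u * u * (3.0 - 2.0 * u)
    if mf.shape == "z":
        a, b = p
        u = _lin_up(x, a, b)
        v = u * u * (3.0 - 2.0 * u)
        return 1.0 - v
    if mf.shape == "pi":
        a, b, c, d = p
        up = _lin_up(x, a, b)
        dn = _lin_up(x, c, d)
        rise = up * up * (3.0 - 2.0 * up)
        fall = 1.0 - dn * dn * (3.0 - 2.0 * dn)
        return np.minimum(rise, fall)
    raise AssertionError(mf.shape)


@dataclass
class FuzzyVariable:
    """A named input (or Mamdani output) variable with its MFs."""

    name: str
    range: tuple[float, float]
    mfs: list[MembershipFunction] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.range
        if not lo < hi:
            raise ValueError(f"variable {self.name!r}: empty range")

    def mf_index(self, name: str) -> int:
        for i, mf in enumerate(self.mfs):
            if mf.name == name:
                return i
        raise KeyError(f"variable {self.name!r} has no MF named {name!r}")


@dataclass
class Consequent:
    """Rule consequent: an output MF (Mamdani), a constant, or a linear
    form ``z = p1*x1 + ... + pk*xk + r`` (first-order Sugeno)."""

    kind: Literal["mf", "constant", "linear"]
    mf_index: Optional[int] = None
    value: Optional[float] = None
    coeffs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.kind == "mf" and self.mf_index is None:
            raise ValueError("mf consequent needs an mf_index")
        if self.kind == "constant" and self.value is None:
            raise ValueError("constant consequent needs a value")
        if self.kind == "linear":
            if self.coeffs is None or len(self.coeffs) < 1:
                raise ValueError("linear consequent needs coefficients [p1..pk, r]")
            self.coeffs = tuple(float(c) for c in self.coeffs)


@dataclass
class Rule:
    """One grid rule: an MF index per input (None = don't care) and a consequent."""

    antecedent: tuple[Optional[int], ...]
    consequent: Consequent
    dummy: bool = False
    name: str = ""


@dataclass
class FuzzySystem:
    """A Mamdani- or Sugeno-flavored fuzzy inference system."""

    flavor: Literal["mamdani", "sugeno"]
    inputs: list[FuzzyVariable]
    rules: list[Rule]
    output: Optional[FuzzyVariable] = None  # mamdani only
    t_norm: Literal["product", "min"] = "product"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flavor not in ("mamdani", "sugeno"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "mamdani" and self.output is None:
            raise ValueError("a Mamdani system needs an output variable")
        if self.t_norm not in ("product", "min"):
            raise ValueError(f"unknown t-norm {self.t_norm!r}")
        k = len(self.inputs)
        for r in self.rules:
            if len(r.antecedent) != k:
                raise ValueError("rule antecedent length must equal the input count")
            for i, m in enumerate(r.antecedent):
                if m is not None and not 0 <= m < len(self.inputs[i].mfs):
                    raise ValueError(f"rule references missing MF {m} of input {i}")
            if r.consequent.kind == "mf":
                if self.output is None or not 0 <= r.consequent.mf_index < len(self.output.mfs):
                    raise ValueError("mf consequent references a missing output MF")
            if r.consequent.kind == "linear" and len(r.consequent.coeffs) != k + 1:
                raise ValueError("linear consequent needs #inputs + 1 coefficients")

    @property
    def feature_names(self) -> list[str]:
        return [v.name for v in self.inputs]

    @property
    def sentinel(self) -> float:
        return float(self.metadata.get("virtual_sentinel", VIRTUAL_SENTINEL))

    def copy(self) -> "FuzzySystem":
        return copy.deepcopy(self)


# ----------------------------------------------------------------------
# inference
# ----------------------------------------------------------------------
def _as_2d(fis: FuzzySystem, inputs) -> np.ndarray:
    X = np.asarray(inputs, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != len(fis.inputs):
        raise ValueError(f"expected {len(fis.inputs)} inputs, got {X.shape[1]}")
    return X, single


def membership_grid(fis: FuzzySystem, X: np.ndarray) -> list[np.ndarray]:
    """Per input variable: (n_samples, n_mfs) membership degrees.

    Inputs equal to the virtual sentinel are masked: they belong to no
    fuzzy set of that variable (degree 0 everywhere).
    """
    grids = []
    for i, var in enumerate(fis.inputs):
        xi = X[:, i]
        g = np.column_stack([mf_eval(mf, xi) for mf in var.mfs])
        g[xi == fis.sentinel] = 0.0
        grids.append(g)
    return grids


def fire_rules(fis: FuzzySystem, inputs) -> np.ndarray:
    """Firing strength of every rule for the given input vector(s).

    Returns shape (n_rules,) for a single input vector or
    (n_samples, n_rules) for a batch; strengths lie in [0, 1].
    """
    X, single = _as_2d(fis, inputs)
    grids = membership_grid(fis, X)
    n = X.shape[0]
    W = np.empty((n, len(fis.rules)))
    for r, rule in enumerate(fis.rules):
        degs = [grids[i][:, m] for i, m in enumerate(rule.antecedent) if m is not None]
        if not degs:
            W[:, r] = 1.0
        elif fis.t_norm == "product":
            W[:, r] = np.prod(degs, axis=0)
        else:
            W[:, r] = np.min(degs, axis=0)
    return W[0] if single else W


def consequent_values(fis: FuzzySystem, X: np.ndarray) -> np.ndarray:
    """Crisp consequent value z_r of every rule at every sample, (n, n_rules).

    Sentinel-masked inputs contribute nothing to linear consequents (their
    term is dropped), so a complex-exercise rule over other features is
    unaffected by masked columns.
    """
    n = X.shape[0]
    Xeff = np.where(X == fis.sentinel, 0.0, X)
    Z = np.empty((n, len(fis.rules)))
    for r, rule in enumerate(fis.rules):
        c = rule.consequent
        if c.kind == "constant":
            Z[:, r] = c.value
        elif c.kind == "linear":
            p = np.asarray(c.coeffs[:-1])
            Z[:, r] = Xeff @ p + c.coeffs[-1]
        else:
            raise ValueError("Mamdani MF consequents have no crisp value; convert first")
    return Z


def sugeno_infer(fis: FuzzySystem, inputs, return_firing: bool = False):
    """Weighted-average defuzzification of a Sugeno system.

    Output is ``sum(w_r * z_r) / sum(w_r)``.  Samples with zero total
    firing (inputs outside every MF support) get NaN — the outlier flag —
    rather than an exception.  With ``return_firing=True`` also returns
    the total firing strength per sample as a diagnostic.
    """
    if fis.flavor != "sugeno":
        raise ValueError("sugeno_infer needs a Sugeno-flavored system")
    X, single = _as_2d(fis, inputs)
    W = np.atleast_2d(fire_rules(fis, X))
    Z = consequent_values(fis, X)
    total = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(total > ZERO_FIRING_EPS, (W * Z).sum(axis=1) / total, np.nan)
    if single:
        y, total = y[0], total[0]
    return (y, total) if return_firing else y


def mamdani_infer(fis: FuzzySystem, inputs, resolution: int = 1001) -> np.ndarray:
    """Min-implication / max-aggregation / discrete-centroid defuzzification.

    ``resolution`` is the number of grid points over the output range
    (≥ 100).  Zero aggregated area yields NaN (outlier flag).
    """
    if fis.flavor != "mamdani":
        raise ValueError("mamdani_infer needs a Mamdani-flavored system")
    if resolution < 100:
        raise ValueError("resolution must be at least 100")
    X, single = _as_2d(fis, inputs)
    W = np.atleast_2d(fire_rules(fis, X))
    ys = np.linspace(fis.output.range[0], fis.output.range[1], resolution)
    curves = np.stack([mf_eval(mf, ys) for mf in fis.output.mfs])  # (n_mfs, res)
    out = np.empty(X.shape[0])
    for s in range(X.shape[0]):
        agg = np.zeros(resolution)
        for r, rule in enumerate(fis.rules):
            if rule.consequent.kind != "mf":
                raise ValueError("Mamdani inference needs MF consequents")
            clipped = np.minimum(W[s, r], curves[rule.consequent.mf_index])
            agg = np.maximum(agg, clipped)
        area = np.trapezoid(agg, ys)
        out[s] = np.trapezoid(agg * ys, ys) / area if area > ZERO_FIRING_EPS else np.nan
    return out[0] if single else out


# ----------------------------------------------------------------------
# structural transforms
# ----------------------------------------------------------------------
def mam2sug(fis: FuzzySystem) -> FuzzySystem:
    """Convert a Mamdani system to a zero-order Sugeno system.

    Inputs and rules are kept; each output MF becomes a constant
    consequent at that MF's area centroid.  The t-norm switches to the
    product, the differentiable choice ANFIS training requires.
    """
    if fis.flavor != "mamdani":
        raise ValueError("mam2sug expects a Mamdani system")
    out = fis.copy()
    out.t_norm = "product"
    centroids = [mf.centroid() for mf in fis.output.mfs]
    for rule in out.rules:
        if rule.consequent.kind == "mf":
            rule.consequent = Consequent("constant", value=centroids[rule.consequent.mf_index])
    out.flavor = "sugeno"
    out.output = None
    return out


def grid_complete(
    fis: FuzzySystem, virtual_range: tuple[float, float] = VIRTUAL_RANGE
) -> FuzzySystem:
    """Fill every missing antecedent combination with a dummy rule.

    The completed rule base has exactly ``prod(#MFs per input)`` rules.
    Each added rule gets a fresh virtual consequent placed inside
    ``virtual_range``: for a Mamdani system a small triangular output MF,
    for a Sugeno system a constant at the corresponding position.  Dummy
    rules stay in the base and participate in inference; real data simply
    never lands on their antecedent combinations.
    """
    out = fis.copy()
    seen: dict[tuple, Rule] = {}
    for rule in out.rules:
        key = tuple(rule.antecedent)
        if key in seen:
            raise ValueError(f"duplicate antecedent combination {key}")
        seen[key] = rule
    combos = list(itertools.product(*[range(len(v.mfs)) for v in out.inputs]))
    missing = [c for c in combos if c not in seen]
    if not missing:
        return out
    lo, hi = virtual_range
    width = (hi - lo) / len(missing)
    for k, combo in enumerate(missing):
        center = lo + (k + 0.5) * width
        name = f"null_{k + 1}"
        if out.flavor == "mamdani":
            mf = MembershipFunction(
                "triangle", (center - 0.5 * width, center, center + 0.5 * width), name
            )
            out.output.mfs.append(mf)
            cons = Consequent("mf", mf_index=len(out.output.mfs) - 1)
        else:
            cons = Consequent("constant", value=center)
        out.rules.append(Rule(tuple(combo), cons, dummy=True, name=name))
    return out


# ----------------------------------------------------------------------
# initial FIS design from labeled feature statistics
# ----------------------------------------------------------------------
def _rest_triangle(values: np.ndarray, span: float, name: str) -> MembershipFunction:
    center = float(np.mean(values))
    width = max(3.0 * float(np.std(values)), 0.05 * span, 1e-3)
    return MembershipFunction("triangle", (center - width, center, center + width), name)


def _move_trapezoid(values: np.ndarray, span: float, name: str) -> MembershipFunction:
    lo, hi = float(np.min(values)), float(np.max(values))
    q10, q90 = np.quantile(values, [0.10, 0.90])
    pad = max(0.1 * span, 1e-3)
    a, b, c, d = lo - pad, float(q10), float(q90), hi + pad
    if not a <= b <= c <= d:  # degenerate (near-constant movement values)
        a, b, c, d = sorted((a, b, c, d))
    return MembershipFunction("trapezoid", (a, b, c, d), name)


def build_initial_fis(
    features: pd.DataFrame,
    schedule: MotionSchedule,
    feature_names: Sequence[str],
    output_halfwidth: float = 1.0,
) -> FuzzySystem:
    """Design the initial Mamdani system from per-motion feature statistics.

    ``features`` must carry the selected feature columns and a ``label``
    column decodable by ``schedule``.  The angular-velocity input gets one
    triangle shared by the rest motions (centered on the pooled rest
    readings) plus one MF per movement; the angle input gets one triangle
    per rest posture plus a trapezoid spanning the pooled movement range.
    The output variable gets one triangle per motion, centered in the
    motion's label range, so its centroid is exactly the range midpoint.
    One rule per motion links the dominant MF pair to the motion's output
    MF; the grid is *not* completed here (see :func:`grid_complete`).
    """
    missing = [f for f in feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"feature columns missing from the table: {missing}")
    if "label" not in features.columns:
        raise ValueError("features table needs a 'label' column")
    motions = list(schedule.motions)
    decoded = np.array([schedule.decode_label(v) for v in features["label"].to_numpy()], dtype=object)
    groups = {m.name: features.loc[decoded == m.name] for m in motions}
    empty = [name for name, g in groups.items() if len(g) == 0]
    if empty:
        raise ValueError(f"no samples labeled for motions {empty}")
    rests = [m for m in motions if m.profile == "rest"]
    moves = [m for m in motions if m.profile == "ramp"]

    input_vars: list[FuzzyVariable] = []
    antecedent_of: dict[str, list[int]] = {m.name: [] for m in motions}
    for fname in feature_names:
        col = features[fname].to_numpy(dtype=float)
        span = float(np.ptp(col)) or 1.0
        pad = 0.15 * span
        var = FuzzyVariable(fname, (float(col.min()) - pad, float(col.max()) + pad))
        is_velocity = fname.startswith("rANGV") or fname.startswith("rACC")
        if is_velocity:
            pooled_rest = np.concatenate([groups[m.name][fname].to_numpy() for m in rests])
            var.mfs.append(_rest_triangle(pooled_rest, span, "i_rest"))
            for m in rests:
                antecedent_of[m.name].append(0)
            for m in moves:
                var.mfs.append(_move_trapezoid(groups[m.name][fname].to_numpy(), span, f"i_{m.name}"))
                antecedent_of[m.name].append(len(var.mfs) - 1)
        else:
            for m in rests:
                var.mfs.append(_rest_triangle(groups[m.name][fname].to_numpy(), span, f"i_{m.name}"))
                antecedent_of[m.name].append(len(var.mfs) - 1)
            pooled_move = np.concatenate([groups[m.name][fname].to_numpy() for m in moves])
            var.mfs.append(_move_trapezoid(pooled_move, span, "i_move"))
            for m in moves:
                antecedent_of[m.name].append(len(var.mfs) - 1)
        if len(var.mfs) < 2:
            raise ValueError(f"input {fname!r} ended up with fewer than 2 MFs")
        input_vars.append(var)

    lo = min(m.label_range[0] for m in motions)
    hi = max(m.label_range[1] for m in motions)
    output = FuzzyVariable("motion", (VIRTUAL_RANGE[0], hi))
    rules: list[Rule] = []
    for m in motions:
        c = m.label_midpoint
        output.mfs.append(
            MembershipFunction("triangle", (c - output_halfwidth, c, c + output_halfwidth), f"o_{m.name}")
        )
        rules.append(
            Rule(tuple(antecedent_of[m.name]), Consequent("mf", mf_index=len(output.mfs) - 1),
                 dummy=False, name=f"o_{m.name}")
        )
    return FuzzySystem(
        flavor="mamdani",
        inputs=input_vars,
        rules=rules,
        output=output,
        t_norm="min",
        metadata={
            "exercise_id": schedule.exercise_id,
            "feature_names": list(feature_names),
            "virtual_sentinel": VIRTUAL_SENTINEL,
            "virtual_range": list(VIRTUAL_RANGE),
        },
    )


# ----------------------------------------------------------------------
# FLL-style text export (FuzzyLite dialect; JSON is the canonical format)
# ----------------------------------------------------------------------
_FLL_TERM = {
    "triangle": "Triangle",
    "trapezoid": "Trapezoid",
    "gaussian": "Gaussian",
    "bell": "Bell",
    "sigmoid": "Sigmoid",
    "s": "SShape",
    "z": "ZShape",
    "pi": "PiShape",
}


def to_fll(fis: FuzzySystem) -> str:
    """Render the system in an FLL-like text dialect for interoperability."""
    lines = [f"Engine: {fis.metadata.get('exercise_id', 'fis')}"]
    for var in fis.inputs:
        lines.append(f"InputVariable: {var.name}")
        lines.append(f"  range: {var.range[0]} {var.range[1]}")
        for mf in var.mfs:
            params = " ".join(f"{p:g}" for p in mf.params)
            lines.append(f"  term: {mf.name} {_FLL_TERM[mf.shape]} {params}")
    lines.append("OutputVariable: motion")
    if fis.flavor == "mamdani":
        lines.append(f"  range: {fis.output.range[0]} {fis.output.range[1]}")
        for mf in fis.output.mfs:
            params = " ".join(f"{p:g}" for p in mf.params)
            lines.append(f"  term: {mf.name} {_FLL_TERM[mf.shape]} {params}")
        lines.append("  defuzzifier: Centroid")
    else:
        lines.append("  defuzzifier: WeightedAverage")
        for i, rule in enumerate(fis.rules):
            c = rule.consequent
            if c.kind == "constant":
                lines.append(f"  term: {rule.name or f'z{i + 1}'} Constant {c.value:g}")
            else:
                coeffs = " ".join(f"{v:g}" for v in c.coeffs)
                lines.append(f"  term: {rule.name or f'z{i + 1}'} Linear {coeffs}")
    lines.append("RuleBlock:")
    for i, rule in enumerate(fis.rules):
        parts = []
        for j, m in enumerate(rule.antecedent):
            if m is not None:
                parts.append(f"{fis.inputs[j].name} is {fis.inputs[j].mfs[m].name or f'mf{m}'}")
        ant = " and ".join(parts) if parts else "any"
        if fis.flavor == "mamdani":
            cons = fis.output.mfs[rule.consequent.mf_index].name
        else:
            cons = rule.name or f"z{i + 1}"
        lines.append(f"  rule: if {ant} then motion is {cons}")
    return "\n".join(lines) + "\n"
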