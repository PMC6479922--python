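"""File formats: sensor-stream CSV, feature CSV, schedule JSON, FIS JSON.

CSV files are UTF-8, comma-separated, dot-decimal, with a mandatory
header; a leading ``#`` comment line documents the units.  Floats are
written with 17 significant digits so write∘read is lossless.  Readers
validate rather than coerce: wrong columns or non-monotone timestamps are
rejected with the offending line number.

The canonical fuzzy-system format is a versioned JSON document; an
FLL-style text export is available through :func:`rehabfis.fuzzy.to_fll`.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .fuzzy import Consequent, FuzzySystem, FuzzyVariable, MembershipFunction, MF_SHAPES, Rule
from .schedule import MotionSchedule, schedule_from_dict, schedule_to_dict
from .simulate import ImuStream

PathLike = Union[str, Path]

STREAM_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
FIS_SCHEMA_VERSION = 1

_UNITS_COMMENT = "# t: s; ax..az: g; gx..gz: deg/s; label: motion-label units\n"


# ----------------------------------------------------------------------
# sensor streams
# ----------------------------------------------------------------------
def write_stream_csv(stream: ImuStream, path: PathLike) -> None:
    df = stream.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_UNITS_COMMENT)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_stream_csv(path: PathLike) -> ImuStream:
    df = _read_csv(path, STREAM_COLUMNS, optional=["label"])
    _check_monotone_t(df, path)
    return ImuStream.from_frame(df)


def _read_csv(path: PathLike, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    extra = [c for c in cols if c not in required and c not in optional]
    if missing or extra:
        raise ValueError(
            f"{path}: bad header; missing columns {missing}, unexpected columns {extra}"
        )
    return df


def _check_monotone_t(df: pd.DataFrame, path: PathLike) -> None:
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +3: 1-based, header line, units comment line
        raise ValueError(f"{path}: non-monotone timestamp at line {int(bad[0]) + 3}")


def write_features_csv(features: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# t: s; rACC*: g; rANGV*: deg/s; rANG*: deg; label: motion-label units\n")
        features.to_csv(fh, index=False, float_format="%.17g")


def read_features_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "t" not in df.columns:
        raise ValueError(f"{path}: feature files need a 't' column")
    _check_monotone_t(df, path)
    return df


# ----------------------------------------------------------------------
# schedules
# ----------------------------------------------------------------------
def write_schedule_json(schedule: MotionSchedule, path: PathLike) -> None:
    Path(path).write_text(json.dumps(schedule_to_dict(schedule), indent=2), encoding="utf-8")


def read_schedule_json(path: PathLike) -> MotionSchedule:
    return schedule_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ----------------------------------------------------------------------
# fuzzy systems
# ----------------------------------------------------------------------
def fis_to_dict(fis: FuzzySystem) -> dict:
    def mf_dict(mf: MembershipFunction) -> dict:
        return {"name": mf.name, "shape": mf.shape, "params": list(mf.params)}

    def var_dict(var: FuzzyVariable) -> dict:
        return {"name": var.name, "range": list(var.range), "mfs": [mf_dict(m) for m in var.mfs]}

    def rule_dict(rule: Rule) -> dict:
        c = rule.consequent
        if c.kind == "mf":
            cons = {"kind": "mf", "mf_index": c.mf_index}
        elif c.kind == "constant":
            cons = {"kind": "constant", "value": c.value}
        else:
            cons = {"kind": "linear", "coeffs": list(c.coeffs)}
        return {
            "antecedent": list(rule.antecedent),
            "consequent": cons,
            "dummy": rule.dummy,
            "name": rule.name,
        }

    doc = {
        "schema_version": FIS_SCHEMA_VERSION,
        "flavor": fis.flavor,
        "t_norm": fis.t_norm,
        "inputs": [var_dict(v) for v in fis.inputs],
        "rules": [rule_dict(r) for r in fis.rules],
        "metadata": fis.metadata,
    }
    if fis.output is not None:
        doc["output"] = var_dict(fis.output)
    return doc


def _reject(pointer: str, msg: str):
    raise ValueError(f"invalid FIS document at {pointer}: {msg}")


def fis_from_dict(doc: dict) -> FuzzySystem:
    if not isinstance(doc, dict):
        _reject("/", "expected a JSON object")
    if doc.get("schema_version") != FIS_SCHEMA_VERSION:
        _reject("/schema_version", f"expected {FIS_SCHEMA_VERSION}, got {doc.get('schema_version')!r}")
    if doc.get("flavor") not in ("mamdani", "sugeno"):
        _reject("/flavor", f"expected 'mamdani' or 'sugeno', got {doc.get('flavor')!r}")

    def parse_mf(d: dict, pointer: str) -> MembershipFunction:
        if d.get("shape") not in MF_SHAPES:
            _reject(f"{pointer}/shape", f"unknown shape {d.get('shape')!r}")
        try:
            return MembershipFunction(d["shape"], tuple(d["params"]), d.get("name", ""))
        except (KeyError, TypeError, ValueError) as exc:
            _reject(pointer, str(exc))

    def parse_var(d: dict, pointer: str) -> FuzzyVariable:
        try:
            rng = (float(d["range"][0]), float(d["range"][1]))
        except (KeyError, TypeError, IndexError):
            _reject(f"{pointer}/range", "expected [lo, hi]")
        mfs = [parse_mf(m, f"{pointer}/mfs/{i}") for i, m in enumerate(d.get("mfs", []))]
        return FuzzyVariable(d.get("name", ""), rng, mfs)

    inputs = [parse_var(v, f"/inputs/{i}") for i, v in enumerate(doc.get("inputs", []))]
    output = parse_var(doc["output"], "/output") if "output" in doc else None

    rules = []
    for i, rd in enumerate(doc.get("rules", [])):
        cd = rd.get("consequent", {})
        kind = cd.get("kind")
        if kind == "mf":
            cons = Consequent("mf", mf_index=int(cd["mf_index"]))
        elif kind == "constant":
            cons = Consequent("constant", value=float(cd["value"]))
        elif kind == "linear":
            cons = Consequent("linear", coeffs=tuple(cd["coeffs"]))
        else:
            _reject(f"/rules/{i}/consequent/kind", f"unknown kind {kind!r}")
        ant = tuple(None if a is None else int(a) for a in rd.get("antecedent", []))
        rules.append(Rule(ant, cons, dummy=bool(rd.get("dummy", False)), name=rd.get("name", "")))

    try:
        return FuzzySystem(
            flavor=doc["flavor"],
            inputs=inputs,
            rules=rules,
            output=output,
            t_norm=doc.get("t_norm", "product"),
            metadata=doc.get("metadata", {}),
        )
    except ValueError as exc:
        _reject("/", str(exc))


def write_fis_json(fis: FuzzySystem, path: PathLike) -> None:
    Path(path).write_text(json.dumps(fis_to_dict(fis), indent=2), encoding="utf-8")


def read_fis_json(path: PathLike) -> FuzzySystem:
    return fis_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ----------------------------------------------------------------------
# packaged fixtures
# ----------------------------------------------------------------------
def load_fixture_fis(name: str = "flex_ext_table3") -> FuzzySystem:
    """Load a packaged fuzzy system, e.g. the published trained
    flexion-extension system (``flex_ext_table3``)."""
    text = resources.files("rehabfis.fixtures").joinpath(f"{name}.json").read_text("utf-8")
    return fis_from_dict(json.loads(text))


def load_fixture_json(name: str) -> dict:
    """Load a packaged JSON fixture by stem name."""
    text = resources.files("rehabfis.fixtures").joinpath(f"{name}.json").read_text("utf-8")
    return json.loads(text)
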