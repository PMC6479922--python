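"""Shared fixtures: synthetic streams and fuzzy systems for exercise A."""

import itertools

import numpy as np
import pytest

import rehabfis as rf
from rehabfis.fuzzy import Consequent, FuzzySystem, FuzzyVariable, MembershipFunction, Rule


@pytest.fixture(scope="session")
def spec_a():
    return rf.exercise_spec("A")


@pytest.fixture(scope="session")
def noiseless_a(spec_a):
    """Noiseless exercise-A stream at 100 Hz with its feature table."""
    cfg = rf.SimulationConfig(frequency=100.0, noise_sd_accel=0.0, noise_sd_gyro=0.0, seed=1)
    stream, labels = rf.simulate_exercise(spec_a, cfg)
    feats = rf.relative_features(stream, rf.calibrate_origin(stream))
    return stream, feats


@pytest.fixture(scope="session")
def initial_fis_a(spec_a, noiseless_a):
    _, feats = noiseless_a
    return rf.build_initial_fis(feats, spec_a.schedule, ["rANGVx", "rANGx"])


@pytest.fixture(scope="session")
def sugeno_a(initial_fis_a):
    return rf.grid_complete(rf.mam2sug(initial_fis_a))


@pytest.fixture(scope="session")
def trained_a(spec_a, sugeno_a, noiseless_a):
    _, feats = noiseless_a
    X = feats[["rANGVx", "rANGx"]].to_numpy()
    y = feats["label"].to_numpy()
    return rf.train(sugeno_a, (X, y), rf.TrainingConfig(epochs=15)).trained


def planted_sugeno(seed: int = 1) -> FuzzySystem:
    """A known 2-input, 9-rule first-order Sugeno system on [-2, 2]^2."""
    rng = np.random.default_rng(seed)
    inputs = []
    for i in range(2):
        mfs = [MembershipFunction("gaussian", (c, 0.6), f"m{j}")
               for j, c in enumerate([-1.0, 0.0, 1.0])]
        inputs.append(FuzzyVariable(f"x{i + 1}", (-2.0, 2.0), mfs))
    rules = [Rule(combo, Consequent("linear", coeffs=tuple(rng.normal(size=3))))
             for combo in itertools.product(range(3), range(3))]
    return FuzzySystem("sugeno", inputs, rules, t_norm="product")


def planted_design(n_per_center: int = 60, seed: int = 0) -> np.ndarray:
    """Inputs clustered at the 9 rule centers so every rule is excited."""
    rng = np.random.default_rng(seed)
    centers = np.array(list(itertools.product([-1, 0, 1], [-1, 0, 1])), dtype=float)
    return np.concatenate([c + rng.normal(0, 0.25, size=(n_per_center, 2)) for c in centers])
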