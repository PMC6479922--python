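"""The staged workflow: simulate → features → initial FIS → train →
recognize → evaluate, as one deterministic, seedable call.

This is the programmatic counterpart of the CLI ``run`` command and the
quickest way to exercise the whole model on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np

from . import features as feat
from .anfis import TrainingConfig, train
from .evaluate import adaptable_rate, confusion, middle_of_second, quartile_rates, rates, recognize, strict_rate
from .fuzzy import FuzzySystem, build_initial_fis, grid_complete, mam2sug
from .schedule import EXERCISE_FEATURES
from .simulate import SimulationConfig, exercise_spec, simulate_exercise

logger = logging.getLogger("rehabfis")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one end-to-end run on synthetic data."""

    exercise_id: str = "A"
    frequency: float = 100.0
    cycles: int = 5
    seed: int = 0
    noise_sd_accel: float = 0.02
    noise_sd_gyro: float = 1.0
    epochs: int = 30
    step_size: float = 0.01
    test_cycles: int = 1
    boundary_fraction: float = 0.10


def pipeline_run(config: RunConfig = RunConfig()) -> dict:
    """Run the full pipeline and return a JSON-serializable report.

    A training stream (``cycles`` cycles) fits the system; a fresh test
    stream (``test_cycles`` cycles, different noise seed) is recognized
    and scored with the adaptable, quartile and confusion schemes.  The
    same config and seed always produce an identical report.
    """
    ex = config.exercise_id.upper()
    feature_names = list(EXERCISE_FEATURES[ex])

    logger.info("simulate: exercise %s, %g Hz, %d cycles", ex, config.frequency, config.cycles)
    spec = exercise_spec(ex, cycles=config.cycles)
    sim_cfg = SimulationConfig(
        frequency=config.frequency,
        noise_sd_accel=config.noise_sd_accel,
        noise_sd_gyro=config.noise_sd_gyro,
        seed=config.seed,
    )
    stream, _ = simulate_exercise(spec, sim_cfg)

    logger.info("features: calibrating origin and deriving relative features")
    origin = feat.calibrate_origin(stream)
    table = feat.relative_features(stream, origin)

    logger.info("init-fis: building the initial Mamdani system from motion statistics")
    initial = build_initial_fis(table, spec.schedule, feature_names)
    sugeno = grid_complete(mam2sug(initial))

    logger.info("train: hybrid ANFIS training, %d epochs", config.epochs)
    X = table[feature_names].to_numpy()
    y = table["label"].to_numpy()
    result = train(sugeno, (X, y), TrainingConfig(epochs=config.epochs,
                                                  step_size=config.step_size,
                                                  seed=config.seed))

    logger.info("recognize: scoring a held-out test stream")
    test_spec = exercise_spec(ex, cycles=config.test_cycles)
    test_cfg = SimulationConfig(
        frequency=config.frequency,
        noise_sd_accel=config.noise_sd_accel,
        noise_sd_gyro=config.noise_sd_gyro,
        seed=config.seed + 1,
    )
    test_stream, _ = simulate_exercise(test_spec, test_cfg)
    test_table = feat.relative_features(test_stream, feat.calibrate_origin(test_stream))
    series = recognize(result.trained, test_table, test_spec.schedule)

    adaptable = adaptable_rate(series, test_spec.schedule, config.boundary_fraction)
    quartile = quartile_rates(series, test_spec.schedule)
    strict = strict_rate(series)
    decisions = middle_of_second(series, test_spec.schedule)
    exercise_ranges = [m.label_range for m in test_spec.schedule.motions]
    conf = confusion(decisions, test_spec.schedule, exercise_ranges)

    return {
        "exercise_id": ex,
        "config": {
            "frequency": config.frequency,
            "cycles": config.cycles,
            "test_cycles": config.test_cycles,
            "seed": config.seed,
            "noise_sd_accel": config.noise_sd_accel,
            "noise_sd_gyro": config.noise_sd_gyro,
            "epochs": config.epochs,
            "step_size": config.step_size,
        },
        "n_train_samples": int(len(stream)),
        "n_test_samples": int(len(test_stream)),
        "rmse_trace": [float(v) for v in result.rmse_trace],
        "final_rmse": float(result.rmse_trace[-1]) if result.rmse_trace else None,
        "strict_rates": strict,
        "adaptable_rates": adaptable,
        "quartile_rates": {str(k): v for k, v in quartile.items()},
        "confusion": {"tp": conf.tp, "fn": conf.fn, "fp": conf.fp, "tn": conf.tn},
        "confusion_rates": rates(conf),
        "outlier_fraction": float(np.mean(np.isnan(series["label"].to_numpy(dtype=float)))),
    }


def trained_system(config: RunConfig = RunConfig()) -> FuzzySystem:
    """Convenience: train and return just the fitted system."""
    ex = config.exercise_id.upper()
    feature_names = list(EXERCISE_FEATURES[ex])
    spec = exercise_spec(ex, cycles=config.cycles)
    stream, _ = simulate_exercise(
        spec,
        SimulationConfig(frequency=config.frequency, noise_sd_accel=config.noise_sd_accel,
                         noise_sd_gyro=config.noise_sd_gyro, seed=config.seed),
    )
    table = feat.relative_features(stream, feat.calibrate_origin(stream))
    sugeno = grid_complete(mam2sug(build_initial_fis(table, spec.schedule, feature_names)))
    X = table[feature_names].to_numpy()
    y = table["label"].to_numpy()
    return train(sugeno, (X, y), TrainingConfig(epochs=config.epochs,
                                                step_size=config.step_size,
                                                seed=config.seed)).trained
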