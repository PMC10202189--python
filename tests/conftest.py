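"""Shared fixtures: tiny synthetic cultivations and a small trained model.

Everything is generated programmatically and seeded; the session-scoped
trained model keeps the expensive work out of individual tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deepcrop.model import DeepCropConfig
from deepcrop.synthetic import CultivationScenario, derive_seed, make_cultivation
from deepcrop.training import TrainingSettings
from deepcrop.workbench import ExperimentConfig, run_experiment_in_memory


def tiny_model_config(**overrides) -> DeepCropConfig:
    base = dict(
        memory_length=3,
        d_model=16,
        n_heads=2,
        n_encoder_blocks=1,
        n_decoder_blocks=1,
        kernel_sizes=(1, 3),
        d_ff=32,
        dropout=0.1,
        seed=0,
    )
    base.update(overrides)
    return DeepCropConfig(**base)


def tiny_scenarios(seed: int = 7, n_days: int = 45) -> list[CultivationScenario]:
    return [
        CultivationScenario(
            name=f"c{i}",
            year=2020 + i // 2,
            start_day_of_year=60 + 100 * (i % 2),
            n_days=n_days,
            planting_density=3.5,
            seed=derive_seed(seed, f"c{i}"),
        )
        for i in range(3)
    ]


def tiny_experiment_config(seed: int = 7) -> ExperimentConfig:
    return ExperimentConfig(
        seed=seed,
        scenarios=tiny_scenarios(seed),
        train_scenarios=("c0", "c1"),
        test_scenario="c2",
        model=tiny_model_config(),
        training=TrainingSettings(epochs=3, batch_size=32),
        n_augment_draws=2,
    )


@pytest.fixture(scope="session")
def tiny_config() -> ExperimentConfig:
    return tiny_experiment_config()


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    """One small end-to-end experiment (train + simulate + evaluate)."""
    return run_experiment_in_memory(tiny_config.copy())


@pytest.fixture(scope="session")
def small_cultivation():
    """A 60-day cultivation with environment, truth and observations."""
    scenario = CultivationScenario(name="fix", n_days=60, seed=11)
    return make_cultivation(scenario)


@pytest.fixture()
def constant_env():
    """Flat environment: T=20, RH=70, radiation 100 W/m2 from 06:00-18:00."""
    index = pd.date_range("2020-03-01", periods=10 * 24, freq="h")
    rad = np.where((index.hour >= 6) & (index.hour < 18), 100.0, 0.0)
    frame = pd.DataFrame(
        {
            "temperature_c": 20.0,
            "relative_humidity_pct": 70.0,
            "radiation_w_m2": rad,
        },
        index=index,
    )
    from deepcrop.env_features import EnvSeries

    return EnvSeries(frame)
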