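"""Shared fixtures.

The trained localizer is expensive (a few thousand gradient steps on one
CPU), so it is built once per session and shared between the parameter-
recovery and end-to-end evaluation tests.
"""

import numpy as np
import pytest

from ogmap import (
    LocalizerConfig,
    SimulationConfig,
    build_localizer,
    train_localizer,
)

SCALED_TRAIN_STEPS = 3000
SCALED_BATCH = 64


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """The study conditions: 335 bp/px, 1/4096 density, sigma 1.5 px, SNR 2.33."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def trained_localizer(sim_config):
    """Localizer trained at the scaled-down schedule (3000 steps, batch 64)."""
    cfg = LocalizerConfig(
        base_channels=12,
        training_steps=SCALED_TRAIN_STEPS,
        batch_size=SCALED_BATCH,
        seed=7,
    )
    model = build_localizer(cfg)
    model, history = train_localizer(model, sim_config, cfg)
    return model, history
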