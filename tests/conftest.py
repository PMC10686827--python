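"""Shared fixtures: schedules, training sets and a trained desk-scale denoiser.

The trained denoiser is session-scoped because fitting it (streaming ridge
regression over noised helices) takes a few seconds and several test modules
share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from bbdiff import (DiffusionSchedule, PolymerPrior, make_ideal_helix,
                    train_denoiser)


@pytest.fixture(scope="session")
def schedule() -> DiffusionSchedule:
    return DiffusionSchedule(n_steps=150)


@pytest.fixture(scope="session")
def helix_training_set():
    lengths = np.random.default_rng(0).integers(30, 80, 60)
    return [make_ideal_helix(int(n), seed=i, jitter=0.15)
            for i, n in enumerate(lengths)]


@pytest.fixture(scope="session")
def helix_test_set():
    lengths = np.random.default_rng(1).integers(30, 80, 10)
    return [make_ideal_helix(int(n), seed=1000 + i, jitter=0.15)
            for i, n in enumerate(lengths)]


@pytest.fixture(scope="session")
def trained_denoiser(schedule, helix_training_set):
    return train_denoiser(helix_training_set, schedule, PolymerPrior(2),
                          n_epochs=6, seed=3)
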