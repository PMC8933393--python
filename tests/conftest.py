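"""Shared fixtures: small payoffs/populations plus the session-scoped
desk-scale study used by the acceptance tests (trained once, reused)."""

from __future__ import annotations

import numpy as np
import pytest

import banditlens as bl
from banditlens import pipeline as pl


@pytest.fixture(scope="session")
def payoff():
    return bl.task.generate_payoff_structure(150, seed=11)


@pytest.fixture(scope="session")
def small_population(payoff):
    """60 mixed agents with occasional missed trials; quick to simulate."""
    return bl.agents.generate_population(
        60,
        payoffs=[payoff],
        episode_config=bl.task.EpisodeConfig(n_trials=150, miss_probability=0.01),
        seed=21,
    )


@pytest.fixture(scope="session")
def desk_config():
    """The desk-scale study conditions shared by the acceptance checks."""
    # 300 epochs is the faithful training recipe; the reward sensitivity of
    # the exploratory net develops long after the pattern structure is
    # learned, so recipe-dependent checks must not truncate training.
    return pl.RunConfig(n_participants=240, epochs=300, seed=2026)


@pytest.fixture(scope="session")
def desk_records(desk_config):
    return pl.simulate_stage(desk_config)


@pytest.fixture(scope="session")
def desk_split(desk_records, desk_config):
    """A single 80/20 participant split (first of five folds)."""
    folds = bl.dataset.split_by_participant(
        desk_records, k=5, seed=pl.substream(desk_config.seed, "folds")
    )
    return folds[0]


@pytest.fixture(scope="session")
def desk_models(desk_records, desk_split, desk_config):
    """All three models trained/fitted on the split's training participants.

    This is the expensive fixture (a few minutes of LSTM training); every
    test that needs a trained network shares it.
    """
    return pl.train_models_on_split(desk_records, desk_split, desk_config)


@pytest.fixture(scope="session")
def desk_predictions(desk_records, desk_split, desk_models, desk_config):
    return pl.evaluate_split(desk_records, desk_split, desk_models, desk_config)
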