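"""Shared fixtures: synthetic repertoires and toy trained models.

The two training fixtures are session-scoped because training, even at toy
scale, dominates suite runtime; every consumer treats the returned models
as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import abdiff as ab
from abdiff.training import TrainConfig, train

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Toy study conditions: a 2-layer / 32-hidden denoiser with a 16-step
#: schedule, trained on 200 synthetic heavy chains for 30 epochs. These are
#: the desk-scale stand-ins for the reference configuration (12 layers /
#: 1024 hidden / 512 steps on millions of sequences).
TOY_T = 16
TOY_MODEL_KW = dict(n_layers=2, n_heads=2, hidden_size=32, dropout=0.0, T=TOY_T)
TOY_TRAIN_KW = dict(batch_size=64, learning_rate=3e-3, weight_decay=0.0, seed=0)
TOY_N_TRAIN = 200
TOY_EPOCHS = 30


@pytest.fixture(scope="session")
def heavy_profile():
    return ab.build_profile("H", seed=11)


@pytest.fixture(scope="session")
def heavy_repertoire(heavy_profile):
    return ab.sample_repertoire(heavy_profile, TOY_N_TRAIN, seed=12)


@pytest.fixture(scope="session")
def toy_schedule():
    return ab.make_schedule(TOY_T)


@pytest.fixture(scope="session")
def toy_trained(heavy_repertoire, toy_schedule):
    """Tiny denoiser trained on the synthetic heavy repertoire + its history."""
    model = ab.build_denoiser(ab.DenoiserConfig(**TOY_MODEL_KW, seed=0))
    model, history = train(
        model,
        heavy_repertoire,
        TrainConfig(epochs=TOY_EPOCHS, **TOY_TRAIN_KW),
        toy_schedule,
    )
    return model, history


@pytest.fixture(scope="session")
def memorization_target(heavy_profile):
    return ab.sample_repertoire(heavy_profile, 1, seed=77, id_prefix="memo")[0]


@pytest.fixture(scope="session")
def memorized_model(memorization_target, toy_schedule):
    """Tiny denoiser overfit to a single repeated sequence."""
    reps = [
        ab.AlignedChain(
            id=f"rep_{i}",
            sequence=memorization_target.sequence,
            chain_type="H",
        )
        for i in range(64)
    ]
    model = ab.build_denoiser(ab.DenoiserConfig(**TOY_MODEL_KW, seed=1))
    model, history = train(
        model,
        reps,
        TrainConfig(batch_size=64, learning_rate=1e-2, weight_decay=0.0,
                    epochs=60, seed=1),
        toy_schedule,
    )
    return model, history


def fr_identity(a: str, b: str, chain_type: str) -> float:
    """Fraction of FR columns at which two aligned sequences agree."""
    fr = ~ab.cdr_mask(chain_type).columns
    aa = np.array(list(a))[fr]
    bb = np.array(list(b))[fr]
    return float((aa == bb).mean())


@pytest.fixture(scope="session")
def fr_identity_fn():
    return fr_identity
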