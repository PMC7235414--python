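"""Shared fixtures: small, fast synthetic subjects reused across tests."""

import logging

import numpy as np
import pytest

from gammareplay import SynthConfig, generate_session
from gammareplay.pipeline import RunConfig, run_subject

logging.getLogger("gammareplay").setLevel(logging.ERROR)


def fast_synth_config(seed: int = 7, **overrides) -> SynthConfig:
    """Desk-scale subject: 8 depth contacts at 250 Hz, 1-min rest,
    12 + 12 sleep epochs, baseline motor-window rate 0.05 pre and 0.20
    post (a reactivating subject)."""
    fields = dict(
        n_channels=8,
        fs=250.0,
        motor_channel_fraction=0.25,
        rest_duration=60.0,
        sleep_epochs_pre=12,
        sleep_epochs_post=12,
        true_motor_window_rate_pre=0.05,
        true_motor_window_rate_post=0.20,
        seed=seed,
    )
    fields.update(overrides)
    return SynthConfig(**fields)


@pytest.fixture(scope="session")
def fast_bundle():
    return generate_session(fast_synth_config())


@pytest.fixture(scope="session")
def fast_report():
    cfg = fast_synth_config()
    return run_subject(RunConfig(synth=cfg, seed=cfg.seed, modes=("all",)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
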