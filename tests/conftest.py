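"""Shared fixtures: synthetic trials generated once per session."""

import warnings

import numpy as np
import pytest

from swimkin.synthetic import (
    StudyTrial,
    SwimmerParams,
    TrialDesign,
    emit_tracks,
    generate_midline_sequence,
)

DESIGN = TrialDesign("fish1", 1, "light", "intact", 1)


@pytest.fixture(scope="session")
def default_params():
    """The study's reference trial: f=2.5 Hz, A=0.08 BL, λ=0.6 BL, U=0.5 BL/s,
    fin 3.5 Hz, 500 fps, 2 s, 1 px jitter."""
    return SwimmerParams(rng_seed=7)


@pytest.fixture(scope="session")
def default_trial(default_params):
    return StudyTrial(DESIGN, default_params)


@pytest.fixture(scope="session")
def default_midlines(default_params):
    return generate_midline_sequence(default_params)


@pytest.fixture(scope="session")
def default_track(default_params, default_midlines):
    return emit_tracks(default_midlines, default_params)


@pytest.fixture(scope="session")
def clean_params():
    """Jitter-free variant for geometric oracles."""
    return SwimmerParams(rng_seed=0, jitter_sd=0.0)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
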