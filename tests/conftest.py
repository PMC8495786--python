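"""Shared fixtures.

The expensive artefacts — training clips, the trained two-submodel
ensemble, and the classified synthetic survey — are built once per
session and shared, so the end-to-end tests stay within a few minutes.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from tinamou.experiments import (
    FIXTURE_ARCH,
    FIXTURE_SPEC_CONFIG,
    run_recovery_experiment,
)
from tinamou.species import fixture_templates
from tinamou.synth import generate_training_clips

logging.getLogger("tinamou").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def spec_config():
    """Fixture-scale spectrogram settings (32-px images, survey band)."""
    return FIXTURE_SPEC_CONFIG


@pytest.fixture(scope="session")
def templates4():
    return fixture_templates(4)


@pytest.fixture(scope="session")
def clip_dataset(templates4):
    """64 clips/class over 4 species + junk, stratified train/val split."""
    clips = generate_training_clips(templates4, 64, seed=101)
    clips.split_train_validation(seed=102)
    return clips


@pytest.fixture(scope="session")
def recovery(tmp_path_factory):
    """Full synthetic-survey pipeline run (shared across e2e tests)."""
    out = tmp_path_factory.mktemp("survey")
    return run_recovery_experiment(out, seed=7)


@pytest.fixture(scope="session")
def trained_ensemble(recovery):
    return recovery.submodels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
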