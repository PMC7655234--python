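"""Shared fixtures: phantom anatomy, small datasets, and one full study run."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cinemotion.study import StudyConfig, run_study, simulate_dataset
from cinemotion.synthetic import make_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def textured_image(phantom):
    """Phantom reference image (its fixed tissue texture is part of it)."""
    return phantom.reference_image


@pytest.fixture(scope="session")
def small_dataset():
    """A short (20 s) default-parameter acquisition for signal-level tests."""
    from dataclasses import replace

    cfg = StudyConfig()
    cfg = replace(cfg, acquisition=replace(cfg.acquisition, duration_s=20.0))
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def default_run():
    """One complete default study run (seed 1): simulate, extract, evaluate.

    Session-scoped because the surrogate-slice registrations dominate the
    cost; several modules assert different facets of the same run.
    """
    return run_study(StudyConfig(), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
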