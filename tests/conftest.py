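"""Shared fixtures: trained knee model bundles and rendered phantoms.

Training is cheap (sub-second per bundle) but shared at session scope so
the suite trains each landmark-count/laterality combination exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from htoplan.geometry import Laterality
from htoplan.phantom import render, sample_specs
from htoplan.training import train_knee_bundle

TRAIN_SEED = 100


@pytest.fixture(scope="session")
def bundle_right_59():
    return train_knee_bundle(laterality=Laterality.RIGHT, n_train=12,
                             landmark_count=59, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def bundle_left_59():
    return train_knee_bundle(laterality=Laterality.LEFT, n_train=12,
                             landmark_count=59, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def bundles_by_count():
    """Right-leg bundles for each canonical landmark count."""
    return {
        n: train_knee_bundle(laterality=Laterality.RIGHT, n_train=12,
                             landmark_count=n, seed=TRAIN_SEED)
        for n in (17, 31, 59)
    }


@pytest.fixture(scope="session")
def clean_phantom():
    """One clean right-leg phantom with a mid-range correction angle."""
    spec = sample_specs(1, angle_distribution=12.0, seed=42)[0]
    img, truth = render(spec)
    return spec, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
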