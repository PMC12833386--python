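"""Shared fixtures: speckle textures and phantom geometry reused across tests.

The expensive 64-cube speckle phantom is session-scoped; tests that deform it
create their own warped counterparts.
"""
from __future__ import annotations

import numpy as np
import pytest

from spinedvc.phantom import make_speckle_phantom, make_spine_phantom

SPACING = 0.58


@pytest.fixture(scope="session")
def speckle64():
    """(volume, texture) of the reference 64-cube speckle phantom."""
    return make_speckle_phantom(64, SPACING, 3000, seed=1)


@pytest.fixture(scope="session")
def spine2():
    """(volume, mask, landmarks, truth) of a 2-level spine phantom."""
    return make_spine_phantom(level_count=2, spacing=1.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
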