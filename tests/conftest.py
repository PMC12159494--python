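"""Shared fixtures: desk-scale grids, atlas, and simulated scans."""

from __future__ import annotations

import numpy as np
import pytest

from vasowave.core import AcquisitionSpec
from vasowave.atlas import build_atlas
from vasowave import synth


@pytest.fixture(scope="session")
def spec64():
    """Desk-scale resting acquisition: 64x64 px, 10 min."""
    return AcquisitionSpec(64, 64, 1500)


@pytest.fixture(scope="session")
def spec64_short():
    return AcquisitionSpec(64, 64, 750)


@pytest.fixture(scope="session")
def atlas64(spec64):
    return build_atlas(spec64)


@pytest.fixture(scope="session")
def quiet_baseline(atlas64, spec64_short):
    """Low-noise baseline movie reused by injection tests."""
    return synth.simulate_baseline(
        atlas64, spec64_short, synth.NoiseSpec(0.0, 0.0), seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
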