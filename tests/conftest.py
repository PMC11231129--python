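"""Shared fixtures: compact phantom configurations sized so the full suite
runs on one CPU core, and small random volumes for filter tests."""

from __future__ import annotations

import numpy as np
import pytest

from petbf.phantom import LesionSpec, PhantomConfig, generate
from petbf.volume_io import Volume


def small_phantom_config(seed: int, gate_count: int = 8, shape=(48, 48, 32),
                         peaks=(3.0, 8.0, 16.0)) -> PhantomConfig:
    """A liver-field-of-view phantom small enough for repeated filtering.

    Geometry is the default phantom scaled to a 48 x 48 x 32 matrix; the
    lesion ladder spans liver-comparable to high contrast (FLR roughly
    1.7 / 5 / 10 after resolution blur).
    """
    return PhantomConfig(
        shape=shape,
        gate_count=gate_count,
        liver_center=(79.2, 79.2, 32.0),
        liver_semiaxes=(60.0, 50.0, 24.0),
        lesions=(
            LesionSpec((55.0, 70.0, 26.0), 9.0, peaks[0]),
            LesionSpec((105.0, 70.0, 38.0), 9.0, peaks[1]),
            LesionSpec((79.2, 105.0, 32.0), 9.0, peaks[2]),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def phantom_small():
    """One 8-gate phantom shared by read-only tests."""
    return generate(small_phantom_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_volume(rng):
    return Volume(rng.random((8, 8, 8)) * 5.0, (3.3, 3.3, 2.0))
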