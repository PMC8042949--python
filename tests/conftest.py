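import numpy as np
import pytest

from sscppi import (
    EncodingConfig,
    ProteinRecord,
    STANDARD_RESIDUES,
    make_fixture_suite,
)


@pytest.fixture(scope="session")
def fixtures():
    return make_fixture_suite(seed=11)


@pytest.fixture(scope="session")
def small_config():
    """A reduced-geometry encoder config: 8x8 grid, 32 slots per protein."""
    return EncodingConfig(max_len=32, min_len=4, grid_side=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, n):
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=n))


@pytest.fixture
def random_records(rng):
    return [
        ProteinRecord(f"P{i:02d}", random_sequence(rng, int(rng.integers(25, 60))))
        for i in range(12)
    ]
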