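"""Shared fixtures: compact synthetic inputs reused across test modules."""

import numpy as np
import pytest

from hdsynapse.synthgen import FieldSpec, gen_synapse_field


@pytest.fixture(scope="session")
def small_field_spec():
    """A compact field: fast to render yet dense enough to detect puncta."""
    return FieldSpec(
        field_size_um=(9.6, 9.6, 3.0),
        voxel_size_um=(0.1, 0.1, 0.3),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_field(small_field_spec):
    return gen_synapse_field(small_field_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
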