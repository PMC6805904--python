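import numpy as np
import pytest

from meioloop import (
    CHR13_CENTROMERE_BP,
    CHR13_LENGTH_BP,
    ContactMatrix,
    make_chromosome_spec,
)


@pytest.fixture(scope="session")
def chr13_spec():
    return make_chromosome_spec("chr13", CHR13_LENGTH_BP, CHR13_CENTROMERE_BP)


@pytest.fixture(scope="session")
def toy_specs():
    """Two small chromosomes for multi-chromosome statistics."""
    return [
        make_chromosome_spec("chrA", 100_000, 40_000),
        make_chromosome_spec("chrB", 80_000, 30_000),
    ]


def make_matrix(specs, bin_bp=2000, fill=1.0):
    m = ContactMatrix.zeros(specs, bin_bp)
    m.counts[:] = fill
    return m


@pytest.fixture
def uniform_matrix(toy_specs):
    return make_matrix(toy_specs)
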