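import pytest

from bacscreen.pooling_design import (
    build_matrix_design,
    build_single_plate_design,
)


@pytest.fixture(scope="session")
def plate_design():
    """Canonical 18-pool single-plate design (built once; deterministic)."""
    return build_single_plate_design()


@pytest.fixture(scope="session")
def matrix25():
    """Canonical 5x5 matrix design for a full 25-plate superpool."""
    return build_matrix_design(25)
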