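import pytest

from cdisorb import (
    ECOMITE_CELL,
    MALEIC_ACID,
    TABLE_PARAMS_MALEIC,
)


@pytest.fixture(scope="session")
def acid():
    """Maleic acid: pKa 1.92/6.23, M = 116.07 g/mol."""
    return MALEIC_ACID


@pytest.fixture(scope="session")
def params():
    """Fitted Moreau parameters for maleic acid on the studied electrodes."""
    return TABLE_PARAMS_MALEIC


@pytest.fixture(scope="session")
def cell():
    """The commercial flow-by cell: Cg 45 F/g, 2 x 1.66 g electrodes."""
    return ECOMITE_CELL
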