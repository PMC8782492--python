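import numpy as np
import pytest

from springpulse.migration_response import atlantic_rim_table
from springpulse.synthetic_data import SyntheticScenario

RDB_TEXT = """\
# U.S. Geological Survey daily values
# retrieved: synthetic fixture
agency_cd\tsite_no\tdatetime\t123_00060_00003\t123_00060_00003_cd
5s\t15s\t20d\t14n\t10s
USGS\t09253000\t2010-01-01\t10.5\tA
USGS\t09253000\t2010-01-02\tIce\t
USGS\t09253000\t2010-01-03\t11.0 e\tA e
USGS\t09253000\t2010-01-04\t12.25\tA
USGS\t09253000\t2010-01-05\t13\tP
"""


@pytest.fixture
def rdb_file(tmp_path):
    path = tmp_path / "dv.rdb"
    path.write_text(RDB_TEXT)
    return str(path)


@pytest.fixture(scope="session")
def herd_table():
    """The packaged Atlantic Rim herd-year summary."""
    return atlantic_rim_table()


@pytest.fixture
def scenario():
    return SyntheticScenario(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
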