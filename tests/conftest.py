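from datetime import date, datetime

import pytest

from empark.config import EngineConfig

DAY = date(2021, 3, 1)


def ts(hour, minute=0, day=0):
    """Timestamp on 2021-03-01 (+day offset)."""
    base = datetime(2021, 3, 1 + day, hour % 24, minute)
    return base


@pytest.fixture
def config():
    return EngineConfig()
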