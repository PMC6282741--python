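import numpy as np
import pytest

from fecalflow.engine import SOURCES, ExposureLedger
from fecalflow.synthetic import default_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def run_config():
    """A complete default configuration shared across tests."""
    return default_config()


def make_ledger(ingestion=None, direct=None, nh_series=None, horizon=840.0,
                record_events=False) -> ExposureLedger:
    """Hand-built ledger with consistent counters for output-layer tests.

    ``ingestion`` maps source -> total ingested count; ``direct`` maps
    source -> the portion of it that was direct.  The emitted counter is
    set so the conservation audit passes (everything ingested).
    """
    led = ExposureLedger(record_events=record_events, horizon_min=horizon)
    ingestion = ingestion or {}
    direct = direct or {}
    for s, c in ingestion.items():
        assert s in SOURCES
        d = int(direct.get(s, 0))
        led.emitted[s] += int(c)
        led.ingested_direct[s] += d
        led.ingested_indirect[s] += int(c) - d
    if nh_series is None:
        nh_series = [(0.0, 0)]
    for t, v in nh_series:
        led.record_nh(t, v)
    return led
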