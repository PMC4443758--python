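import numpy as np
import pytest

from nmjphys import Trace


@pytest.fixture
def flat_trace() -> Trace:
    return Trace(np.zeros(2000), dt=1e-4, channel="voltage_mV")


@pytest.fixture
def ramp_trace() -> Trace:
    """0..1 mV linear ramp over exactly 1 s at 1 kHz."""
    n = 1000
    return Trace(np.arange(n) / (n - 1), dt=1e-3, channel="voltage_mV")
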