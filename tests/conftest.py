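import numpy as np
import pytest

from znfbind.binding import NM, RateConstants

# rate-constant sets spanning the measured range (slow/fast association,
# 9-17 h dissociation halftimes)
MEASUREMENT_RATES = {
    1: RateConstants(k_on=135.0, k_off=2.2e-5, dk_on=5.0, dk_off=0.2e-5),
    2: RateConstants(k_on=725.0, k_off=1.1e-5, dk_on=35.0, dk_off=0.3e-5),
    3: RateConstants(k_on=1908.0, k_off=1.4e-5, dk_on=130.0, dk_off=0.1e-5),
}


@pytest.fixture(params=[1, 2, 3], ids=lambda i: f"measurement{i}")
def measured_rates(request) -> RateConstants:
    return MEASUREMENT_RATES[request.param]


@pytest.fixture
def rates_slow() -> RateConstants:
    return MEASUREMENT_RATES[1]


@pytest.fixture
def rates_fast() -> RateConstants:
    return MEASUREMENT_RATES[2]


@pytest.fixture
def concentration_ladder_nM() -> tuple[float, ...]:
    return (78.0, 156.0, 312.0, 625.0, 1250.0)
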