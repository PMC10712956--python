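import numpy as np
import pytest

from mitotherm import build_scenario, synthgen
from mitotherm.synthgen import (GtempProbeModel, MtyProbeModel,
                                gtemp_staircase_protocol, mty_protocol)


@pytest.fixture
def mty_probe():
    return MtyProbeModel()


@pytest.fixture
def gtemp_probe():
    return GtempProbeModel()


@pytest.fixture
def oligomycin_scenario():
    """Standard oligomycin run: 18 °C elevation abolished, ±3 °C staircase."""
    return build_scenario("inhibitor")


@pytest.fixture
def exact_oligomycin_scenario():
    """Zero-lag protocol and fast decay: elevation tail < 1e-6 °C at the
    response window, so zero-noise recovery is exact."""
    return build_scenario(
        "inhibitor", dict(decay_tau=100.0),
        protocol=mty_protocol(37.0, lag=0.0),
    )


@pytest.fixture
def exact_gtemp_calibration_trace(gtemp_probe):
    """Zero-noise, zero-lag, zero-elevation 30→42 °C staircase record."""
    scn = build_scenario(
        "baseline", dict(initial_elevation=0.0, duration=1800.0),
        protocol=gtemp_staircase_protocol(lag=0.0),
    )
    return synthgen.render_gtemp_trace(scn, gtemp_probe)


@pytest.fixture
def gtemp_calibration_trace(gtemp_probe):
    """Realistic calibration record: oligomycin decay then lagged staircase."""
    scn = build_scenario(
        "inhibitor", dict(drug_time=60.0, duration=1800.0),
        protocol=gtemp_staircase_protocol(),
    )
    return synthgen.render_gtemp_trace(scn, gtemp_probe)
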