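import numpy as np
import pytest

from adaptivent import PatientMechanics, VentilatorSettings

#: Cohort-typical baseline used across the suite: compliance 55, insp
#: resistance 11, expiratory time constant 0.82 s, PBW 74 kg.
BASELINE_VE = 7.5 * 74.0 * 15.3  # ml/min
BASELINE_VDA = 2.2 * 74.0  # ml


@pytest.fixture
def typical_mechanics() -> PatientMechanics:
    return PatientMechanics.create(
        crs=55.0, r_insp=11.0, rce=0.82, pbw=74.0, vco2=250.0, etco2_gradient=5.0
    )


@pytest.fixture
def slow_settings() -> VentilatorSettings:
    """Low-rate settings with full inflation and exhalation."""
    return VentilatorSettings(peep=5.0, delta_p=10.0, rr=4.0, ti=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231101)
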