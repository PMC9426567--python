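import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def ideal_readout():
    """Noiseless readout with crosstalk off: channels invert exactly."""
    from mixcult.synthetic import ReadoutParams

    return ReadoutParams().ideal()


@pytest.fixture
def default_readout():
    from mixcult.synthetic import ReadoutParams

    return ReadoutParams()


@pytest.fixture
def coculture_layout():
    """Salvager/dependent coculture plus the two single-marker controls."""
    from mixcult.synthetic import StrainParams

    sal = StrainParams("salvager", 0.47, 0.0, 5e-3, 0.5, "CFP")
    dep = StrainParams("dependent", 0.40, 4.0, 5e-3, 0.05, "YFP")
    sal_mono = StrainParams("salvager", 0.47, 0.0, 1e-2, 0.5, "CFP")
    dep_mono = StrainParams("dependent", 0.40, 4.0, 1e-2, 0.05, "YFP")
    return {"A1": [sal, dep], "B1": [sal_mono], "C1": [dep_mono]}


@pytest.fixture
def time_grid():
    from mixcult.synthetic import default_time_grid

    return default_time_grid()
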