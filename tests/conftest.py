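import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def sample_times():
    return np.geomspace(60.0, 86_400.0, 12)


@pytest.fixture
def design():
    from oxcascade.synthdata import ExperimentDesign

    return ExperimentDesign()


@pytest.fixture
def uracil_direct_model():
    """The hydroxymethyl-uracil cascade truth: k1 = 0.66, k2 = 0.43."""
    from oxcascade import RateParameters, build_cascade

    return build_cascade(
        "direct", RateParameters(k_TM=1.75e-5, k_hm=0.66, k_f=0.43)
    )


@pytest.fixture
def aza_hydrate_model():
    """The 6-aza-uracil cascade truth: k1 = 1.87, hydrate k = 0.24, K = 0.09."""
    from oxcascade import RateParameters, build_cascade

    return build_cascade(
        "hydrate_route",
        RateParameters(k_TM=1.75e-5, k_hm=1.87, k_dhm=0.24, k_for=1000.0),
        0.09,
    )
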