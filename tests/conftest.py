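import pytest

from pulletreq.allometry import AllometricParams, Compartment
from pulletreq.datasets import reference_bundle
from pulletreq.growth import GrowthParams


@pytest.fixture(scope="session")
def vb_params() -> GrowthParams:
    """Published Von Bertalanffy growth parameters."""
    return GrowthParams("von_bertalanffy", 1412.418, 0.748, 0.024)


@pytest.fixture(scope="session")
def gompertz_params() -> GrowthParams:
    return GrowthParams("gompertz", 1261.652, 3.521, 0.034)


@pytest.fixture(scope="session")
def carcass_power() -> AllometricParams:
    return AllometricParams("power", 0.181, 1.007, target=Compartment.CARCASS)


@pytest.fixture(scope="session")
def feather_quadratic() -> AllometricParams:
    return AllometricParams("quadratic", -3.393, 0.089, -1.46e-5, target=Compartment.FEATHER)


@pytest.fixture(scope="session")
def bundle():
    """Model bundle assembled from the published reference parameters."""
    return reference_bundle()
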