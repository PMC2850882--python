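import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import p38compete as pc

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=15,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """Default constants (in-house kcat_MK2 = 2.4 s^-1)."""
    return pc.KineticParameters()


@pytest.fixture(scope="session")
def params_lit():
    """Constants with the literature kcat_MK2 = 0.17 s^-1, the value that
    keeps the simulated 30-min MK2 readout in the assay's linear range."""
    return pc.KineticParameters(kcat_mk2=pc.LITERATURE_KCAT_MK2)


@pytest.fixture(scope="session")
def selective():
    return pc.InhibitorSpec(
        ki=1.0, selectivity_f=0.99, inhibitor_class="substrate_selective"
    )


@pytest.fixture(scope="session")
def classical():
    return pc.InhibitorSpec(ki=1.0, inhibitor_class="classical")


@pytest.fixture(scope="session")
def base_network(params):
    return pc.build_network(params)


def fitted_ic50(dr):
    """4PL IC50 of a clean simulated dose-response (raises if unconverged)."""
    fit = pc.fit_hill(dr.doses, dr.normalized)
    return fit.ic50_or_raise()


@pytest.fixture(scope="session")
def ic50_of():
    return fitted_ic50
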