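import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from coastbgc import ModelVersion, ParameterSet, StateVector, make_initial_state

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def state_p(params) -> StateVector:
    return make_initial_state(ModelVersion.P, "oligotrophic-summer")


@pytest.fixture
def state_nop(params) -> StateVector:
    return make_initial_state(ModelVersion.noP, "oligotrophic-summer")


@pytest.fixture
def p_saturated_pair(params):
    """A P-version state with pinned-saturated phosphorus plus the noP
    state sharing every C/N variable, for structural-equivalence checks."""
    sp = make_initial_state(ModelVersion.P, "oligotrophic-summer")
    sp["Pb"] = params.phyto.QP_max * sp["Cb"]
    sp["Pba"] = params.bacteria.QP_max * sp["Cba"]
    sp["PO4"] = 10.0
    sn = make_initial_state(ModelVersion.noP, "oligotrophic-summer")
    for v in sn.variables:
        sn[v] = sp[v]
    return sp, sn


def rel_diff(a, b, floor=1e-12):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
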