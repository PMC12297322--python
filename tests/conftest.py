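import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nsclineage as nl

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def unit_params():
    """Unit-rate parameters for hand-checkable arithmetic."""
    return nl.ModelParameters(
        r0=1.0, K=1.0, b0=0.5, beta=1e-9, pA=1.0, pT=1.0, delta=1.0,
        NSC0=2.0,
    )


@pytest.fixture
def eq_params():
    """Parameters with a hand-derivable positive equilibrium (A=50, Q~86.6)."""
    return nl.ModelParameters(
        r0=1.0, K=100.0, b0=0.75, beta=0.01, pA=1.0, pT=1.0, delta=1.0,
    )


@pytest.fixture
def wt_params():
    return nl.default_true_parameters()


@pytest.fixture
def scenario2():
    """qNSCs promote / aNSCs inhibit activation, qNSCs inhibit self-renewal."""
    return nl.get_scenario("r(Q,A),b(Q)")


@pytest.fixture
def scenario1():
    return nl.get_scenario("r(Q,A),b(A)")


@pytest.fixture
def small_wt_dataset():
    """Cheap synthetic wild-type dataset shared across estimation tests."""
    cfg = nl.GeneratorConfig(ages=nl.default_ages(6), mice_per_age=3, seed=11)
    return cfg, nl.generate_dataset(cfg)
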