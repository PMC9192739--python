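import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protmr.simulate import LDBlock, SimulationConfig, simulate_cohorts

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """A modest two-sample study shared by read-only tests: one 8-variant
    LD block (r = 0.5), ten proteins in two modules, one cis-driven causal
    protein."""
    cfg = SimulationConfig(
        n_exposure=1500, n_outcome=1500,
        blocks=[LDBlock(8, 0.5, (0.2, 0.4))],
        n_proteins=10, n_modules=2, module_r=0.4,
        cis_effects={"P0000": {"b0v0": 0.6}},
        causal_thetas={"P0000": 0.4},
        baseline_prevalence=0.2, seed=3)
    return simulate_cohorts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
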