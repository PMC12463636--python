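import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrdlite.config import load_gate_config, load_population_config
from mrdlite.synthetic_marrow import apply_preparation, generate_tube_pair, make_sample_spec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pop_cfg():
    return load_population_config()


@pytest.fixture(scope="session")
def gate_cfg():
    return load_gate_config()


@pytest.fixture(scope="session")
def marrow_5pct(pop_cfg):
    """Bulk-lysis day-15 marrow with a 5% (of nucleated) blast burden."""
    spec = apply_preparation(
        make_sample_spec(0.05, n_events=100_000, seed=11, config=pop_cfg), config=pop_cfg)
    return generate_tube_pair(spec, config=pop_cfg)


@pytest.fixture(scope="session")
def marrow_blast_free(pop_cfg):
    """Bulk-lysis marrow with zero blasts (null sample)."""
    spec = apply_preparation(
        make_sample_spec(0.0, n_events=100_000, seed=12, config=pop_cfg), config=pop_cfg)
    return generate_tube_pair(spec, config=pop_cfg)


def rel_err(est: float, true: float) -> float:
    return abs(est - true) / abs(true)
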