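import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_zone_case():
    """One ~21k-cell two-zone study slide shared across the session."""
    from iopn_tme.pipeline import simulate_two_zone_case

    cells, truth, spec = simulate_two_zone_case(seed=11)
    return cells, truth, spec


@pytest.fixture(scope="session")
def two_zone_regions(two_zone_case):
    """Region-discovery result on the shared two-zone slide."""
    from iopn_tme.pipeline import analyze_regions, tissue_roi

    cells, _, spec = two_zone_case
    return analyze_regions(cells, roi=tissue_roi(spec), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
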