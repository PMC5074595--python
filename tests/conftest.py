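import numpy as np
import pytest

import switchwave as sw


@pytest.fixture(scope="session")
def ref_params() -> sw.ToggleParams:
    return sw.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def noise_unit() -> sw.NoiseParams:
    """Unit burst sizes, Omega = 100."""
    return sw.NoiseParams(omega=100.0, nu_a=1.0, nu_b=1.0)


@pytest.fixture(scope="session")
def bifurcation(ref_params) -> sw.BifurcationResult:
    """Fold points of the reference switch (shared across tests)."""
    return sw.continuation_scan(ref_params, (0.0, 1.5), n_points=61)


@pytest.fixture(scope="session")
def coarse_profiles(ref_params, noise_unit):
    """Coarse B->A and A->B action profiles across the bistable zone."""
    grid = np.round(np.arange(0.2, 0.91, 0.1), 4)
    ba = sw.action_profile("BA", ref_params, noise_unit, grid, n_path=301)
    ab = sw.action_profile("AB", ref_params, noise_unit, grid, n_path=301)
    return ba, ab
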