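import numpy as np
import pytest

import turnoverlab as tl


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def zero_noise_config():
    return tl.SyntheticStudyConfig(
        noise=tl.simulate.NoiseModel(enrichment_cv=0.0, mass_cv=0.0), seed=7
    )


@pytest.fixture(scope="session")
def param_grid():
    """Kinetic parameter grid spanning loss, gain and near-steady pools."""
    grid = []
    for k_deg in (0.005, 0.019, 0.05, 0.15):
        for p_eq_ratio in (0.25, 0.9, 1.0, 1.3):
            p0 = 150.0
            grid.append(
                tl.KineticParams.from_equilibrium(p0=p0, k_deg=k_deg, p_eq=p0 * p_eq_ratio)
            )
    return grid
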