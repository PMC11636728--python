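import numpy as np
import pytest

import rospace as rs


@pytest.fixture(scope="session")
def mixed_params():
    """Small mixed categorical/numeric space: 5 * 2 * 3 = 30 experiments."""
    return [
        rs.ParameterSpec("ligand", "categorical", ("L0", "L1", "L2", "L3", "L4")),
        rs.ParameterSpec("base", "categorical", ("KOAc", "CsOAc")),
        rs.ParameterSpec("temperature", "numeric", (25.0, 60.0, 90.0)),
    ]


@pytest.fixture(scope="session")
def mixed_space(mixed_params):
    return rs.build_parameter_space(mixed_params)


@pytest.fixture(scope="session")
def small_campaign(mixed_params):
    """Seeded 3-cycle campaign (batch 5) on the 30-point mixed space."""
    truth = rs.planted_truth(
        mixed_params,
        seed=11,
        noise_sd=1.0,
        dominant=("ligand", "L3"),
        interaction=(("ligand", "L3"), ("base", "KOAc")),
    )
    config = rs.CampaignConfig(
        params=tuple(mixed_params),
        truth=truth,
        n_cycles=3,
        batch_size=5,
        seed=21,
    )
    return rs.run_campaign(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
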