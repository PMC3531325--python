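import numpy as np
import pytest

from tomtrust.game import GameConfig


@pytest.fixture(scope="session")
def config():
    """Default 10-round game with the standard five-action grids."""
    return GameConfig()


@pytest.fixture(scope="session")
def toy_configs():
    """Small games (<=2 rounds, <=3 actions/side, <=3 types) for exhaustive
    comparison against the brute-force enumeration oracle."""
    return [
        GameConfig(
            num_rounds=2,
            investor_grid=(0.0, 0.5, 1.0),
            trustee_grid=(0.0, 1.0 / 3.0, 2.0 / 3.0),
            guilt_grid=(0.0, 0.6),
            noise_grid=(1.0,),
        ),
        GameConfig(
            num_rounds=2,
            investor_grid=(0.25, 0.75),
            trustee_grid=(1.0 / 6.0, 0.5, 2.0 / 3.0),
            guilt_grid=(0.0, 0.4, 1.0),
            noise_grid=(0.7,),
        ),
        GameConfig(
            num_rounds=1,
            investor_grid=(0.0, 0.5, 1.0),
            trustee_grid=(0.0, 0.5),
            guilt_grid=(0.2, 0.9),
            noise_grid=(2.0,),
        ),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
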