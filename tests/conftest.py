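import pytest
from hypothesis import settings

from hmcdiff.simulate import SimConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study (16 tumor / 6 normal, 10 Mb, 2 kb bins)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def flat_null_bundle():
    """Flat-profile null: no planted regions, no global shift."""
    return simulate_dataset(
        SimConfig(
            seed=12, n_tumor=8, n_normal=6, global_level_tumor=1.0,
            n_gain=0, n_loss=0, intensity_sigma=0.0, zero_inflation=0.0,
        )
    )
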