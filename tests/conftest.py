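import numpy as np
import pytest

from tbamp.genome import GenomeLayout
from tbamp.sim import SimConfig, make_layout


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def layout(sim_config) -> GenomeLayout:
    return make_layout(sim_config)


@pytest.fixture(scope="session")
def toy_layout() -> GenomeLayout:
    """One 100-Mb chromosome with a centromere at 39.6-40.5 Mb, plus a
    second smaller chromosome."""
    return GenomeLayout(
        lengths={"1": 100_000_000, "2": 60_000_000},
        centromeres={"1": (39_600_000, 40_500_000), "2": (24_000_000, 25_000_000)},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
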