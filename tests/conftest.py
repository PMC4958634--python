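import numpy as np
import pandas as pd
import pytest

from feedquad import SimConfig
from feedquad.synthdata import simulate_expression, simulate_read_depth


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale study emulation used by most unit tests."""
    return SimConfig(
        n_genes=2000,
        n_windows=2000,
        genome_length=6_000_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_expression(small_cfg):
    return simulate_expression(small_cfg)


@pytest.fixture(scope="session")
def small_depth(small_cfg):
    return simulate_read_depth(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def balanced_matrix(rng) -> tuple[pd.DataFrame, dict]:
    """50 random genes x 16 samples, 4 per quadrant."""
    samples = [f"S{i:02d}" for i in range(16)]
    quad = {s: ("HH", "HL", "LL", "LH")[i % 4] for i, s in enumerate(samples)}
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, (50, 16)),
        index=[f"g{i}" for i in range(50)],
        columns=samples,
    )
    return values, quad
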