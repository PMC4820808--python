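import numpy as np
import pytest

from locrep import synthetic
from locrep.discovery import discover_repeats, mask_te


@pytest.fixture(scope="session")
def demo_sim():
    """One small simulated genome with planted truth, shared across tests."""
    cfg = synthetic.demo_config(seed=2)
    assembly, genes, te, truth = synthetic.simulate_genome(cfg)
    return dict(config=cfg, assembly=assembly, genes=genes, te=te, truth=truth)


@pytest.fixture(scope="session")
def demo_discovery(demo_sim):
    masked = mask_te(demo_sim["assembly"], demo_sim["te"])
    return dict(masked=masked, families=discover_repeats(masked))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
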