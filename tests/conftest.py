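import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_campaign():
    """A small simulated campaign shared across read-level tests."""
    import biopanml as bp

    cfg = bp.SimulationConfig(n_clonotypes=50, binder_fraction=0.2, seed=7,
                              read_depth=(800,) * 5, read_error_rate=0.0)
    truth = bp.simulate_repertoire(cfg)
    counts = bp.simulate_panning(truth, cfg)
    return cfg, truth, counts


@pytest.fixture(scope="session")
def truth_labeled_dataset():
    """Factory: oracle-labeled TR dataset from a fresh simulation."""
    import biopanml as bp

    def make(seed=0, n=200, depth=4000, binder_fraction=0.23, config=None):
        cfg = config or bp.SimulationConfig(
            n_clonotypes=n, binder_fraction=binder_fraction, seed=seed,
            read_depth=(depth,) * 5)
        truth = bp.simulate_repertoire(cfg)
        counts = bp.simulate_panning(truth, cfg)
        return bp.truth_tr_dataset(truth, counts)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
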