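import numpy as np
import pytest

from regland.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 1) shared across the session."""
    outdir = tmp_path_factory.mktemp("bundle") / "b"
    manifest = simulate(SimulationConfig(seed=1), outdir)
    return outdir, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
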