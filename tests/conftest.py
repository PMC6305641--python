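import pytest

from fadiv.design import pd20_design
from fadiv.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def design():
    return pd20_design()


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, design):
    """One default-config simulation shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("sim")
    simulate_all(design, SimulationConfig(seed=7), outdir)
    return outdir
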