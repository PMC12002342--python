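import pytest

from mnph import simulate
from mnph.scenario import default_grid, default_scenario


@pytest.fixture(scope="session")
def reference_run():
    """Full-resolution transient solve of the reference treatment scenario
    (dr = dz = 0.5 mm, dt = 1 s, 60 min), shared across tests."""
    return simulate(default_scenario(), default_grid())
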