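import pytest

import trdens as td


@pytest.fixture(scope="session")
def state_15x15():
    """One seeded 15x15 synthetic state shared by read-only tests."""
    config = td.SimConfig(lattice_rows=15, lattice_cols=15, seed=7)
    table, graph = td.simulate_state(config)
    return table, graph, config
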