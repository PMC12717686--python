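import pytest

import adhereroi as ar


@pytest.fixture(scope="session")
def params():
    return ar.default_parameters()


@pytest.fixture(scope="session")
def scenarios():
    """Canonical scenario registry keyed by short handle."""
    table = ar.scenario_table()
    return {
        "baseline": table[0],
        "early": table[1],
        "delayed": table[2],
        "regressive": table[3],
        "adaptive": table[4],
        "low_impact": table[5],
    }


@pytest.fixture(scope="session")
def coarse_params():
    """Coarser grid for scans where sub-percent accuracy is not at stake."""
    return ar.default_parameters().replace(grid_step=0.05)
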