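import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from guildniche.core_io import load_table4_fixture
from guildniche.synthetic_data import simulate_study


@pytest.fixture(scope="session")
def scat_fixture():
    return load_table4_fixture()


@pytest.fixture(scope="session")
def study():
    """One default-scale synthetic study shared across tests (seed 42)."""
    truth, cov, states, histories, records, scats = simulate_study(seed=42)
    return {
        "truth": truth,
        "covariates": cov,
        "states": states,
        "histories": histories,
        "records": records,
        "scats": scats,
    }
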