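import numpy as np
import pandas as pd
import pytest

from sibsurv.io import load_worked_example
from sibsurv.microsim import SimConfig, extract_ssh, run_simulation


@pytest.fixture(scope="session")
def small_pop():
    """A reduced stable population shared across tests."""
    return run_simulation(SimConfig(target_final_size=4000, seed=11))


@pytest.fixture(scope="session")
def small_ssh(small_pop):
    return extract_ssh(small_pop)


@pytest.fixture(scope="session")
def small_full_ssh(small_ssh):
    rng = np.random.default_rng(5)
    return small_ssh.to_full_ssh(rng=rng, n_clusters=25)


@pytest.fixture(scope="session")
def table1():
    return load_worked_example("table1")


@pytest.fixture(scope="session")
def table2():
    return load_worked_example("table2")


@pytest.fixture(scope="session")
def table5():
    return load_worked_example("table5")


@pytest.fixture(scope="session")
def table6():
    return load_worked_example("table6")


@pytest.fixture()
def tiny_ssh():
    """Hand-countable full-SSH rows: one respondent, two adult siblings,
    one of whom died three years before the interview."""
    v = 1200
    return pd.DataFrame(
        {
            "resp_id": [1, 1],
            "resp_birth_cmc": [v - 300, v - 300],
            "cluster": [0, 0],
            "stratum": [0, 0],
            "weight": [1.0, 1.0],
            "interview_cmc": [v, v],
            "sib_sex": ["f", "f"],
            "sib_alive": [True, False],
            "sib_birth_cmc": [v - 320, v - 340],
            "sib_death_cmc": [np.nan, v - 36],
        }
    )
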