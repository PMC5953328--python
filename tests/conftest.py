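import numpy as np
import pytest

from repkit import SimulationConfig, simulate_repertoire
from repkit.airr_io import Rearrangement


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated repertoire shared across tests."""
    return simulate_repertoire(
        SimulationConfig(seed=7, n_records=300, n_clones=30)
    )


def make_record(sequence_id="r1", **kwargs):
    return Rearrangement(sequence_id=sequence_id, **kwargs)


@pytest.fixture()
def record_factory():
    return make_record
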