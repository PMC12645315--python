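import numpy as np
import pandas as pd
import pytest

from regselect import scenarios
from regselect.register import records_to_frame, IndividualRecord
from regselect.simulate import simulate_register


@pytest.fixture(scope="session")
def default_register():
    """A mid-sized register from the default scenario, shared across tests."""
    cfg = scenarios.default_register_config(30_000, seed=11)
    df, truth = simulate_register(cfg)
    return df, truth, cfg


@pytest.fixture()
def tiny_records():
    """A handful of hand-written records covering the main cases."""
    return [
        IndividualRecord("p1", "F", 1950, "primary", 3, 1970, 1978),
        IndividualRecord("p2", "M", 1960, "unknown", 0),
        IndividualRecord("p3", "F", 1950, "tertiary", 1, 1975, 1975),
        IndividualRecord("p4", "M", 1950, "secondary", 2, 1976, 1980),
        IndividualRecord("p5", "F", 1950, "vocational", 0, age_at_death=14),
    ]


@pytest.fixture()
def tiny_frame(tiny_records):
    return records_to_frame(tiny_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
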