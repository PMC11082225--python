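import numpy as np
import pandas as pd
import pytest

from bh3flow import EventTable, GatingConfig, make_preset, simulate_tube


@pytest.fixture(scope="session")
def cll_preset():
    return make_preset("CLL")


@pytest.fixture(scope="session")
def rs_preset():
    return make_preset("RS")


@pytest.fixture
def small_gating_config():
    """Default gates with a QC floor suited to small fixtures."""
    return GatingConfig(min_gated_events=1000)


@pytest.fixture(scope="session")
def cll_bim_tube(cll_preset):
    """One simulated CLL tube under the BIM 10 uM condition (truth-labeled)."""
    return simulate_tube(cll_preset, ("BIM", 10.0), 30000, seed=11)


def ideal_target_table(n=2000, cytc_value=None, seed=0):
    """All-target event table with perfectly in-gate channels.

    Scatter, viability and markers sit mid-gate; the cyt-c channel is a
    constant unless ``cytc_value`` is an array.
    """
    rng = np.random.default_rng(seed)
    cytc = np.full(n, 3500.0) if cytc_value is None else np.asarray(cytc_value, float)
    fsc_a = rng.uniform(40000, 60000, n)
    values = np.column_stack([
        fsc_a,
        fsc_a * 0.97,
        rng.uniform(15000, 30000, n),
        np.full(n, 300.0),
        np.full(n, 9000.0),
        np.full(n, 9000.0),
        cytc,
    ])
    truth = pd.DataFrame({"population": ["target"] * n, "released": [False] * n})
    return EventTable(("FSC-A", "FSC-H", "SSC-A", "Zombie", "CD5", "CD19", "CytC"),
                      values, truth)


@pytest.fixture
def ideal_table():
    return ideal_target_table()
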