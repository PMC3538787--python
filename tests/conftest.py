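import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from devtiming import EventTimingTable, SyntheticSpec, generate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(rows):
    """rows: iterable of (species, event, pc_day, is_primate, event_class)."""
    return EventTimingTable(pd.DataFrame(
        rows, columns=["species", "event", "pc_day", "is_primate", "event_class"]))


@pytest.fixture
def tiny_table():
    """3 species x 4 events, fully observed, one primate, mixed classes."""
    rows = []
    pc = {("mouse", "ev1"): 10.0, ("mouse", "ev2"): 12.0,
          ("mouse", "ev3"): 15.0, ("mouse", "ev4"): 20.0,
          ("rat", "ev1"): 11.0, ("rat", "ev2"): 13.5,
          ("rat", "ev3"): 17.0, ("rat", "ev4"): 23.0,
          ("macaque", "ev1"): 30.0, ("macaque", "ev2"): 38.0,
          ("macaque", "ev3"): 55.0, ("macaque", "ev4"): 80.0}
    classes = {"ev1": "cortical", "ev2": "limbic", "ev3": "other", "ev4": "cortical"}
    for (sp, ev), day in pc.items():
        rows.append((sp, ev, day, sp == "macaque", classes[ev]))
    return make_table(rows)


@pytest.fixture
def dense_noiseless():
    """Dense noiseless 5 x 8 table following the offset-log generative form."""
    spec = SyntheticSpec(n_species=5, n_events=8, n_primates=1, k_true=5.0,
                         noise_sd=0.0, missing_fraction=0.0, seed=42)
    table, truth = generate(spec)
    return table, truth, spec


@pytest.fixture
def sparse_noisy():
    """Sparse noisy 6 x 10 table, the typical small working fixture."""
    spec = SyntheticSpec(n_species=6, n_events=10, n_primates=2, k_true=5.0,
                         noise_sd=0.05, missing_fraction=0.3, seed=7)
    table, truth = generate(spec)
    return table, truth, spec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
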