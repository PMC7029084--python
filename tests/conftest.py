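import numpy as np
import pandas as pd
import pytest

from lhinvar.trait_io import TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """Six species, two groups, one trait with gaps."""
    df = pd.DataFrame({
        "species": [f"Sp {i}" for i in range(1, 7)],
        "group": ["Anura", "Anura", "Anura", "Caudata", "Caudata", "Caudata"],
        "body_mass": [10.0, 100.0, 1000.0, 5.0, 50.0, np.nan],
        "clutch_size": [20.0, 200.0, np.nan, 8.0, 80.0, 800.0],
    })
    return TraitTable(df, {"body_mass": "g", "clutch_size": "count"})


def make_table(mass, trait, name="trait", group="G"):
    n = len(mass)
    df = pd.DataFrame({
        "species": [f"S{i:03d}" for i in range(n)],
        "group": group,
        "body_mass": np.asarray(mass, float),
        name: np.asarray(trait, float),
    })
    return TraitTable(df, {"body_mass": "g", name: "arb"})
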