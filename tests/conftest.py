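import numpy as np
import pandas as pd
import pytest

from hbdkit.panel import GenotypePanel


def make_panel(dosages, scaffold="s1", positions=None, categories=None,
               populations=None, groups=None, depths=None, genetic_pos=None):
    """Small hand-built panel for unit tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": np.asarray(positions),
            "ref": "A",
            "alt": "T",
            "genetic_pos": genetic_pos if genetic_pos is not None else np.nan,
            "category": categories if categories is not None else "unclassified",
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(n_ind)],
            "population": populations if populations is not None else "pop1",
            "group": groups if groups is not None else "g1",
        }
    )
    return GenotypePanel(
        dosages=dosages,
        sites=sites,
        individuals=individuals,
        depths=None if depths is None else np.asarray(depths),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
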