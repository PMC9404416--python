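import datetime as dt

import pandas as pd
import pytest

from herdfert.pedigree import Pedigree
from herdfert.simulate import HerdSimConfig, simulate_herd
from herdfert.tables import RawHerdData


@pytest.fixture
def trio():
    """Offspring with two unrelated founder parents."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["O", "S", "D"],
                "sire": ["S", None, None],
                "dam": ["D", None, None],
                "birth_date": ["2002-01-01", "2000-01-01", "2000-02-01"],
            }
        )
    )


@pytest.fixture
def fullsib_mating():
    """Parents -> two full sibs -> their offspring (F = 0.25)."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["P1", "P2", "S1", "S2", "O"],
                "sire": [None, None, "P1", "P1", "S1"],
                "dam": [None, None, "P2", "P2", "S2"],
            }
        )
    )


@pytest.fixture
def one_cow():
    """One animal: two services, the second conceiving, then a calving."""
    return RawHerdData(
        animal_id="C1",
        herd_id="H1",
        birth_date=dt.date(2000, 1, 1),
        sire_id="S1",
        dam_id="D1",
        services=[
            (dt.date(2001, 5, 31), "failure"),
            (dt.date(2001, 6, 21), "success"),
        ],
        calvings=[(dt.date(2002, 3, 28), 1)],  # 280 d after the 2nd service
    )


@pytest.fixture(scope="session")
def small_herd():
    """A ~450-female synthetic herd with its truth ledger."""
    cfg = HerdSimConfig(n_founders=150, n_generations=3, generation_size=200, seed=42)
    ped, records, truth = simulate_herd(cfg)
    return cfg, ped, records, truth
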