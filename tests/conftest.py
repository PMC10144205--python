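import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cagedemog.demography import LifeTable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_life_table(ages, lx, Mx, hx) -> LifeTable:
    """Assemble a LifeTable from parallel sequences."""
    return LifeTable(
        pd.DataFrame(
            {
                "age_day": np.asarray(ages, dtype=int),
                "lx": np.asarray(lx, dtype=float),
                "Mx": np.asarray(Mx, dtype=float),
                "hx": np.asarray(hx, dtype=float),
            }
        )
    )


@pytest.fixture
def point_mass_table():
    """Reproduction concentrated on a single age (x = 46)."""
    ages = np.arange(0, 52)
    Mx = np.where(ages == 46, 10.0, 0.0)
    hx = np.where(ages == 46, 0.5, 0.0)
    return make_life_table(ages, np.ones(len(ages)), Mx, hx)
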