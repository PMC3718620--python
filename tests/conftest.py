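import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from countyprev import outcomes as oc
from countyprev import synthetic as syn

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid33():
    return syn.make_county_grid(3, 3)


@pytest.fixture(scope="session")
def small_sim():
    """3x3 grid, 2001-2005, identity reporting, minutes present every year."""
    g = syn.make_county_grid(3, 3)
    truth = syn.simulate_truth(g, range(2001, 2006), syn.GenerativeParams(seed=11))
    records = syn.simulate_survey(
        truth, g, 200, reporting_bias=syn.ReportingBias.none(), seed=12,
        odd_year_minutes_only=False,
    )
    return g, truth, records


@pytest.fixture(scope="session")
def derived_small(small_sim):
    g, truth, records = small_sim
    return g, truth, oc.derive_outcomes(records, None)


def make_records(rows):
    """Microdata frame from a list of partial dicts, with sane defaults."""
    defaults = {
        "year": 2001,
        "county_id": "c00_00",
        "sex": "female",
        "age_group": "20-34",
        "race": "white",
        "reported_weight": 70.0,
        "reported_height": 1.7,
        "any_pa": "yes",
        "moderate_min_week": 100.0,
        "vigorous_min_week": 0.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def moran_i(values, neighbors, county_ids):
    """Moran's I by direct summation over the adjacency structure (test oracle)."""
    x = np.asarray([values[c] for c in county_ids], dtype=float)
    z = x - x.mean()
    pos = {c: i for i, c in enumerate(county_ids)}
    num = 0.0
    w_total = 0
    for c in county_ids:
        for b in neighbors[c]:
            num += z[pos[c]] * z[pos[b]]
            w_total += 1
    return (len(x) / w_total) * num / (z @ z)
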