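from datetime import datetime

import pytest

import edtransit as e

GRID_START = datetime(2013, 1, 1, 0, 0)


@pytest.fixture(scope="session")
def reference_truth():
    return e.TruthParams.reference()


@pytest.fixture(scope="session")
def reference_profile():
    return e.ArrivalProfile.reference()


@pytest.fixture(scope="session")
def sim_month(reference_truth, reference_profile):
    """A 30-day simulated census under the reference truth."""
    return e.simulate_census(reference_profile, reference_truth, days=30, seed=424)


@pytest.fixture(scope="session")
def sim_month_design(sim_month):
    return e.build_design(sim_month)


@pytest.fixture(scope="session")
def sim_month_fit(sim_month_design):
    return e.DepartureModel(sim_month_design).fit()
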