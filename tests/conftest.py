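import pytest

from mycotrace import Compartment, ConcentrationRecord, Dataset, load_fixture
from mycotrace.synthetic_data import SyntheticScenario


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_soils")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_mushrooms")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_massbalance")


def soil_pair_dataset(pairs, element="Cd", site="granite"):
    """Build a dataset of (free, bearing) soil concentration pairs."""
    records = []
    for i, (free, bearing) in enumerate(pairs):
        sid = f"{site}-pair{i:02d}"
        records.append(ConcentrationRecord(
            sample_id=sid, site=site, date="2021-07",
            compartment=Compartment.SOIL_FREE, element=element, value=free))
        records.append(ConcentrationRecord(
            sample_id=sid, site=site, date="2021-07",
            compartment=Compartment.SOIL_BEARING, element=element, value=bearing))
    return Dataset(records=records, provenance="test")


def small_scenario(effect=0.8, seed=0, gsd=1.4, pair_gsd=1.05, element="Cd",
                   n_dates=5):
    """3-site x n_dates scenario with one depleted element."""
    sites = {site: {element: (float(m), gsd)}
             for site, m in (("granite", 0.35), ("amphibolite", 0.77),
                             ("serpentinite", 0.73))}
    return SyntheticScenario(
        sites=sites, depletion_effect={element: effect},
        pair_noise_gsd=pair_gsd, n_dates=n_dates, seed=seed)
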