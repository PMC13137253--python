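import pytest
from hypothesis import HealthCheck, settings

from hydralk import forcefield as ff
from hydralk import reparam as rp
from hydralk import thermo_reference as tref
from hydralk.fep_estimator import ThermoState

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ts300() -> ThermoState:
    return ThermoState(T=300.0)


@pytest.fixture(scope="session")
def table1():
    return tref.load_reference("table1_spce")


@pytest.fixture(scope="session")
def table1_records(table1):
    return rp.records_from_frame(table1)


@pytest.fixture(scope="session")
def alkane_sites():
    return ff.load_sites("trappe_ua")


@pytest.fixture(scope="session")
def water_sites():
    return {
        name: list(ff.load_sites(name).values())[0]
        for name in ("spce", "opc3", "opc", "tip4p2005")
    }


@pytest.fixture(scope="session")
def toy_solvent_pair():
    """Toy solvent LJ parameters used across MC tests (see docs/methods.md)."""
    return ff.PairPar(0.4, 0.34, origin="solvent")


@pytest.fixture(scope="session")
def toy_cross_pair():
    """Methane-like solute-solvent cross pair for the toy system."""
    return ff.PairPar(0.9, 0.35)
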