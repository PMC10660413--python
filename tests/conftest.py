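import pytest

from scatniche.samples import FaecalSample
from scatniche.synth import SimulationConfig, default_prey_reference

STUDY_DESIGN = [("East", 2015), ("West", 2015), ("East", 2020), ("West", 2020)]


@pytest.fixture(scope="session")
def prey_ref():
    return default_prey_reference()


@pytest.fixture()
def sim_config():
    return SimulationConfig(seed=42)


def make_sample(sid="s1", area="East", year=2015, **kw):
    return FaecalSample(sid, area, year, **kw)


@pytest.fixture()
def four_samples():
    return [
        make_sample("a", "East", 2015, iom_pct=10.0, fgcm=5.0, prey={"Chital"}),
        make_sample("b", "West", 2015, iom_pct=85.0, ft3m=2.0, prey={"Sambar", "Hare"}),
        make_sample("c", "East", 2020, x=100.0, y=200.0),
        make_sample("d", "West", 2020, iom_pct=79.9, prey={"Hare"}),
    ]
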