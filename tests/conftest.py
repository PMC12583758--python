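import pytest

from livecarbon.factors import default_factors
from livecarbon.panel import PanelRecord
from livecarbon.synthdata import SynthConfig, generate_panel


@pytest.fixture(scope="session")
def factors100():
    return default_factors("GWP100")


@pytest.fixture(scope="session")
def factors20():
    return default_factors("GWP20")


@pytest.fixture
def pig_record():
    """One-city, one-species, one-product record used as the arithmetic fixture."""
    return PanelRecord(
        city="Testville", year=2001,
        inventories={"pig": 100.0},
        outputs={"pork": 2.0},
        feed_factor={"pork": 3.5},
        grain_shares={"corn": 0.6, "wheat": 0.2, "soybean": 0.15},
        elec_cost={"pig": 21.375},
        coal_cost={"pig": 80.0},
        output_value=1.0e6,
    )


@pytest.fixture(scope="session")
def synth_panel():
    """Default-condition synthetic panel shared by read-only tests."""
    return generate_panel(SynthConfig(seed=11))
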