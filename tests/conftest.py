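import numpy as np
import pytest

from efit.climate_io import Co2Table, MonthlyClimate, SiteRecord
from efit.lue_core import LueParams


@pytest.fixture
def params():
    return LueParams()


@pytest.fixture
def uniform_climate():
    """25 degC and 16000 kJ m-2 day-1 every month."""
    return MonthlyClimate(temp=np.full(12, 25.0), srad=np.full(12, 16000.0))


@pytest.fixture
def frozen_climate():
    """All months below freezing."""
    return MonthlyClimate(temp=np.full(12, -10.0), srad=np.full(12, 8000.0))


@pytest.fixture
def co2_400():
    return Co2Table(ppm_by_year={2000: 400.0})


@pytest.fixture
def uniform_site():
    return SiteRecord(site_id="U1", lon=0.0, lat=45.0, year=2000, tnpp_obs=22.0)
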