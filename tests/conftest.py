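import numpy as np
import pytest

import soildoc as sd
from soildoc import column, synthetic


@pytest.fixture
def grid():
    return sd.LayerGrid()


@pytest.fixture
def soil():
    return sd.SoilProperties(clay=0.20, silt=0.35, ph=5.5, zstar=0.35,
                             s_wilt=0.15, s_opt=0.70)


@pytest.fixture
def params():
    return sd.default_params("temperate")


@pytest.fixture
def small_state(grid):
    """A populated column state with uneven stocks in every pool."""
    soc = np.array([
        [40.0, 30.0, 20.0, 10.0],
        [400.0, 300.0, 200.0, 100.0],
        [60.0, 45.0, 30.0, 15.0],
        [900.0, 700.0, 500.0, 300.0],
    ])
    dis = np.array([[5.0, 4.0, 3.0, 2.0], [15.0, 12.0, 9.0, 6.0]])
    ads = 0.5 * dis
    return column.SoilColumnState(
        soc=sd.SocPools(soc, grid=grid),
        doc=sd.DocPools(dis, ads, grid),
    )


@pytest.fixture
def constant_forcing_year():
    return synthetic.constant_forcing(365, dt=86400.0, litter=400.0 / 365.0)


@pytest.fixture
def fast_spinup():
    return column.SpinupConfig(mode="direct", tol=1e-3, max_cycles=400)
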