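import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rootwater import EndMemberSet, IsotopeComposition, VWCProfile

# Catchment-mean compositions (‰ VSMOW) used throughout the worked examples:
# shallow (10 cm) bulk soil water as the surface end member, mean groundwater,
# and mean tree xylem water on dry dates.
SURFACE = IsotopeComposition(-6.2, -45.6)
GROUNDWATER = IsotopeComposition(-8.6, -54.6)
TREE_MEAN = IsotopeComposition(-5.4, -42.7)


@pytest.fixture
def catchment_end_members() -> EndMemberSet:
    return EndMemberSet("catchment", SURFACE, GROUNDWATER, max_depth_cm=120.0)


@pytest.fixture
def uniform_profile() -> VWCProfile:
    """Three sensors at 10/30/50 cm holding constant VWC 0.30 for ten days."""
    idx = pd.date_range("2009-07-01", periods=10, freq="1D")
    depths = np.array([10.0, 30.0, 50.0])
    frame = pd.DataFrame(0.30, index=idx, columns=depths)
    return VWCProfile("SITE", depths, frame)


def daily_precip(values, start="2009-07-01") -> pd.Series:
    idx = pd.date_range(start, periods=len(values), freq="1D")
    return pd.Series(list(values), index=idx, dtype=float)
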