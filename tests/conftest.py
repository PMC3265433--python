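import numpy as np
import pytest

from spinealign.spine_geometry import VERTEBRAE, SpinalCurve


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def straight_curve():
    """All 12 markers collinear on the longitudinal axis."""
    x = np.linspace(500.0, 0.0, len(VERTEBRAE))  # C7 -> L5
    return SpinalCurve(x, np.zeros_like(x), frame="raw")


@pytest.fixture
def toy_stats_groups():
    """Fixed three-group fixture with unequal n and unequal variances."""
    from spinealign.group_stats import GroupSample
    return [
        GroupSample("A", np.array([10.0, 12.0, 14.0, 16.0])),
        GroupSample("B", np.array([11.0, 13.0, 15.0])),
        GroupSample("C", np.array([20.0, 22.0, 24.0, 26.0, 28.0])),
    ]
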