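import numpy as np
import pytest

import thermobrace as tb


@pytest.fixture
def small_thermal():
    """2x2 thermal frame with distinct temperatures."""
    return tb.ThermalFrame(np.array([[30.0, 31.0], [32.0, 33.0]]))


@pytest.fixture
def camera_pair():
    """A pair with the real acquisition geometry: 1440x1080 RGB, 160x120 thermal."""
    rgb = tb.RgbFrame(np.zeros((1080, 1440, 3), dtype=np.uint8))
    thermal = tb.ThermalFrame(np.full((120, 160), 33.0))
    return tb.make_pair(rgb, thermal)


@pytest.fixture
def null_phantom_config():
    """No hot spot, no vertical trend: an exchangeable null between the ROIs."""
    return tb.PhantomConfig(delta_t_c=0.0, gradient_c_per_px=0.0)


def make_scores(ps, direction, labels):
    return [tb.ScoreRecord(p_value=p, direction_ok=d, label=y)
            for p, d, y in zip(ps, direction, labels)]
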