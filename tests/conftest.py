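import numpy as np
import pytest

from inkwindow.image_analysis import ConstructMask


@pytest.fixture
def rect_mask():
    """Perfect axis-aligned rectangle, 1000 x 100 px at 5 µm/px."""
    m = np.zeros((140, 1040), dtype=bool)
    m[20:120, 20:1020] = True
    return ConstructMask(m, um_per_px=5.0, kind="line")


@pytest.fixture
def quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
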