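import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from porescape.pointpattern import ObservationWindow, PointPattern


@pytest.fixture
def square_window():
    """Full 100×100 μm rectangle at 1 μm/px."""
    return ObservationWindow(np.ones((100, 100), dtype=bool), 1.0)


@pytest.fixture
def disc_window():
    """Disc-shaped window (radius 18 px) inside a 40×40 frame."""
    yy, xx = np.mgrid[0:40, 0:40]
    mask = (yy - 19.5) ** 2 + (xx - 19.5) ** 2 <= 18.0**2
    return ObservationWindow(mask, 1.0)


def pattern_on(window, points):
    return PointPattern(np.asarray(points, dtype=float), window)
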