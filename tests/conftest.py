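import numpy as np
import pytest

import pharmstorm as ps


@pytest.fixture
def square_roi():
    """10 x 10 µm analysis square."""
    return ps.PolygonROI.rectangle(0, 0, 10_000, 10_000)


@pytest.fixture
def disk_masks():
    """Three bouton-like disks on a 4 x 4 µm raster at the 10 nm grid."""
    return ps.generate_structure_masks(
        "disks", 3, {"radius_nm": 300.0}, shape=(400, 400), pixel_size=10.0, seed=11
    )


def point_in_polygon_crossing(vertices: np.ndarray, x: float, y: float) -> bool:
    """Brute-force crossing-number point-in-polygon test (test oracle)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
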