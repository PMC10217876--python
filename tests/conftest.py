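import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from sedrisk.data import GBTable, LayerMap, SamplePanel, SiteGeometry


@pytest.fixture
def tiny_panel() -> SamplePanel:
    """One site, one year, every metal and Fe exactly at a GB of 2.0."""
    rows = [
        {"site_id": 1, "year": 2015, "analyte": a, "value": 2.0, "flag": ""}
        for a in ["As", "Cd", "Co", "Cr", "Cu", "Hg", "Mn", "Ni", "Pb", "Zn", "Fe"]
    ]
    return SamplePanel(pd.DataFrame(rows))


@pytest.fixture
def tiny_gb() -> GBTable:
    return GBTable(
        {(1, a): 2.0 for a in ["As", "Cd", "Co", "Cr", "Cu", "Hg", "Mn", "Ni", "Pb", "Zn", "Fe"]}
    )


@pytest.fixture
def straight_site() -> SiteGeometry:
    """Site at the origin with a straight 3 km upstream polyline along +x."""
    return SiteGeometry(
        site_id=1, point=Point(0, 0), upstream_line=LineString([(0, 0), (3000, 0)])
    )


@pytest.fixture
def uniform_background_layer() -> LayerMap:
    """Single huge polygon with Cd background 5.49 (and Fe for EF)."""
    return LayerMap(
        role="background",
        features=[(box(-10000, -10000, 10000, 10000), {"GB_Cd": 5.49, "GB_Fe": 7000.0})],
    )


def random_grid_layer(rng: np.random.Generator, n: int = 10, cell: float = 400.0,
                      origin: tuple[float, float] = (-200.0, -2000.0)) -> LayerMap:
    """n × n grid of random-valued background cells covering the test buffer."""
    x0, y0 = origin
    features = []
    for i in range(n):
        for j in range(n):
            geom = box(x0 + i * cell, y0 + j * cell, x0 + (i + 1) * cell, y0 + (j + 1) * cell)
            features.append((geom, {"GB_X": float(rng.uniform(1.0, 10.0))}))
    return LayerMap(role="background", features=features)
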