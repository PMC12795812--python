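import numpy as np
import pytest
from shapely.geometry import Point, Polygon


@pytest.fixture(scope="session")
def unit_squares():
    """Two disjoint unit squares with analytic hull area 3 and total area 2."""
    return [
        Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]),
        Polygon([(2, 0), (3, 0), (3, 1), (2, 1)]),
    ]


@pytest.fixture(scope="session")
def smooth_blob():
    """Asymmetric smooth closed contour for shape-descriptor tests."""
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    r = 1 + 0.3 * np.cos(2 * t) + 0.15 * np.sin(3 * t) + 0.08 * np.cos(5 * t)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def disk(x, y, r=1.0, n=64):
    return Point(x, y).buffer(r, quad_segs=n)


@pytest.fixture(scope="session")
def rendered_cluster():
    """One default synthetic cluster (two angles + truth), shared by tests."""
    from grapemap.simulate import ClusterSimConfig, simulate_cluster

    cfg = ClusterSimConfig(seed=0, n_artifacts=4)
    masks_per_angle, truth = simulate_cluster(cfg)
    return cfg, masks_per_angle, truth
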