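import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from karea.data_io import SyntheticSpec, generate
from karea.geometry import PointSet


def _rot(a: float) -> np.ndarray:
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


@pytest.fixture
def three_triangles() -> PointSet:
    """Three congruent triangles of area 0.5, pairwise far apart.

    Each copy is rotated differently so the clusters are in generic position
    (no collinear rows across clusters, which would admit zero-area slab
    cuts); in this placement the divisive algorithm recovers the planted
    triangles exactly.
    """
    base = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    base = base - base.mean(axis=0)
    centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    angles = [0.5, 2.0, 4.0]
    coords = np.vstack([base @ _rot(a).T + c for a, c in zip(angles, centers)])
    return PointSet(coords, np.repeat([1, 2, 3], 3))


@pytest.fixture
def two_squares() -> PointSet:
    """Two unit squares with centers 10 apart (8 points)."""
    sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    coords = np.vstack([sq, sq + [10.0, 0.0]])
    return PointSet(coords, np.repeat([1, 2], 4))


# One planted outlier between two clusters in generic position: a wide
# flat-topped cluster below (its shoulder vertices admit a clean separating
# chord) and a narrow cluster above.  The outlier sits between them; adding
# it to the upper cluster grows that hull far less than adding it to the
# lower one.
OUTLIER_LOWER = np.array(
    [[-3.0, 0.0], [3.0, 0.0], [2.0, -1.0], [0.0, -1.5], [-2.2, -1.1]]
)
OUTLIER_UPPER = np.array(
    [[-0.75, 5.0], [0.75, 5.1], [0.5, 6.0], [-0.4, 6.2]]
)
OUTLIER_POINT = np.array([[0.1, 4.2]])


@pytest.fixture
def outlier_fixture():
    coords = np.vstack([OUTLIER_LOWER, OUTLIER_UPPER, OUTLIER_POINT])
    lower = np.arange(len(OUTLIER_LOWER))
    upper = np.arange(len(OUTLIER_LOWER), len(OUTLIER_LOWER) + len(OUTLIER_UPPER))
    outlier = len(coords) - 1
    return PointSet(coords), lower, upper, outlier


def blob_points(seed: int, **kwargs) -> PointSet:
    """Default planted fixture: 4 Gaussian blobs, 50 points each,
    separation ratio 10."""
    return generate(SyntheticSpec(seed=seed, **kwargs)).points
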