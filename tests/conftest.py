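import numpy as np
import pytest
from skbio import DistanceMatrix

from phylosym.datamodel import FeatureTable, SampleMetadata
from phylosym.io import read_newick


@pytest.fixture
def small_table() -> FeatureTable:
    counts = np.array([
        [10, 5, 0, 2],
        [8, 0, 3, 1],
        [0, 7, 6, 0],
    ])
    return FeatureTable(("s1", "s2", "s3"), ("tA", "tB", "tC", "tD"), counts)


@pytest.fixture
def star_tree():
    return read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def metadata_records() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "P01", "sp1", 30.0, 100.0, 3000.0, "Crassulaceae"),
        SampleMetadata("s2", "P01", "sp1", 30.0, 100.0, 3000.0, "Crassulaceae"),
        SampleMetadata("s3", "P02", "sp2", 35.0, 110.0, 900.0, "Papaveraceae"),
    ]


def random_distance_matrix(n: int, rng: np.random.Generator,
                           ids=None) -> DistanceMatrix:
    """Euclidean distances between random points: a valid metric matrix."""
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=ids or [f"L{i}" for i in range(n)])
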