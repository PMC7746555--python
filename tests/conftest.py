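import numpy as np
import pytest

from covnet import SyntheticSpec, generate_cohort


def adjacency(edges, n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


@pytest.fixture
def k3():
    return adjacency([(0, 1), (1, 2), (0, 2)], 3)


@pytest.fixture
def p3():
    return adjacency([(0, 1), (1, 2)], 3)


@pytest.fixture
def star4():
    """S4: one center (node 0) with 3 leaves."""
    return adjacency([(0, 1), (0, 2), (0, 3)], 4)


@pytest.fixture
def k4():
    return adjacency([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)


@pytest.fixture
def k5():
    return adjacency([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)


@pytest.fixture
def two_triangles():
    return adjacency([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)


def ring_lattice(n=20, k=4):
    """Each node connected to its k nearest ring neighbours."""
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            a[i, j] = a[j, i] = 1
    return a


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject, 68-region two-group cohort with block structure."""
    spec = SyntheticSpec(group_sizes=(30, 30), seed=7)
    return generate_cohort(spec)
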