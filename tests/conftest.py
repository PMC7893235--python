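import numpy as np
import pytest

from morphosig.align import gpa
from morphosig.simulate import (make_scheme, make_truth, simulate_dataset)


@pytest.fixture(scope="session")
def small_scheme():
    return make_scheme(12, 5)


@pytest.fixture(scope="session")
def desk_truth(small_scheme):
    return make_truth(small_scheme, seed=0)


@pytest.fixture(scope="session")
def desk_dataset(desk_truth):
    ds, truth = simulate_dataset(desk_truth, n_specimens=30, n_partial=6,
                                 seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def desk_aligned(desk_dataset):
    ds, _ = desk_dataset
    return gpa(ds.complete_subset())


def random_rigid_motion(rng):
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-5, 5, size=3)
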