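import numpy as np
import pytest

from dtialps import (
    PhantomSpec,
    build_phantom,
    default_scheme,
    select_shells,
    synthesize_signals,
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_spec():
    """Smallest grid the default geometry supports — keeps fits fast."""
    return PhantomSpec(grid_shape=(40, 24, 4), glymphatic_coefficient=(1.4, 1.3))


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_truth, scheme):
    return synthesize_signals(small_truth, scheme)


@pytest.fixture(scope="session")
def small_dti(small_dataset):
    """The b ≤ 1,150 sub-dataset actually used for tensor fitting."""
    return select_shells(small_dataset)


def random_spd_tensors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric positive-definite tensors with WM-scale eigenvalues."""
    from scipy.stats import ortho_group

    eig = rng.uniform(0.1e-3, 2.0e-3, size=(n, 3))
    rot = ortho_group.rvs(3, size=n, random_state=np.random.RandomState(rng.integers(2**31)))
    if rot.ndim == 2:
        rot = rot[None]
    return np.einsum("nij,nj,nkj->nik", rot, eig, rot)
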