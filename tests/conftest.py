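import numpy as np
import pytest

from preful3d.phantom import (
    Breathing,
    Drift,
    PhantomSpec,
    build_phantom,
    simulate_acquisition,
)
from preful3d.trajectory import make_trajectory


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        defects=[((14, 23, 26), 5.0, 0.0)],
        drift=Drift(amplitude=0.2),
        noise_sigma=0.000625,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_traj():
    return make_trajectory(8000)


@pytest.fixture(scope="session")
def small_acq(small_truth, small_spec, small_traj):
    return simulate_acquisition(small_truth, small_spec, small_traj, n_spokes=8000)


@pytest.fixture(scope="session")
def static_spec():
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        breathing=Breathing(diaphragm_shift_vox=0.0, period_s=1e9),
        noise_sigma=0.0,
        seed=2,
    )


@pytest.fixture(scope="session")
def static_truth(static_spec):
    return build_phantom(static_spec)


@pytest.fixture(scope="session")
def static_acq(static_truth, static_spec, small_traj):
    return simulate_acquisition(static_truth, static_spec, small_traj, n_spokes=8000)


def brute_force_kmeans_1d(values, k):
    """Optimal 1D k-means by exhaustive search over contiguous partitions of
    the sorted values (the optimum is contiguous in sorted order)."""
    import itertools

    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        cost = 0.0
        labels = np.empty(n, dtype=int)
        for ci in range(k):
            seg = values[bounds[ci]:bounds[ci + 1]]
            cost += ((seg - seg.mean()) ** 2).sum()
            labels[bounds[ci]:bounds[ci + 1]] = ci
        if cost < best[0] - 1e-12:
            best = (cost, labels)
    return values, best[1], best[0]
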