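import numpy as np
import pytest
from hypothesis import settings

import scanpower as sp

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid3() -> sp.Region:
    """3x3 unit-spaced grid, all populations 100."""
    return sp.make_grid_region(sp.GridSpec(rows=3, cols=3, population_model=("uniform", 100.0)))


@pytest.fixture(scope="session")
def grid5() -> sp.Region:
    """5x5 unit-spaced grid, all populations 100."""
    return sp.make_grid_region(sp.GridSpec(rows=5, cols=5, population_model=("uniform", 100.0)))


@pytest.fixture(scope="session")
def grid15() -> sp.Region:
    """The default 15x15 test region (225 SUs, 200 births/SU/year)."""
    return sp.make_grid_region(sp.GridSpec())


def random_region(rng: np.random.Generator, n: int) -> sp.Region:
    """Small region with random centroids and populations for oracles."""
    units = [
        sp.SpatialUnit(
            f"u{k:02d}",
            float(rng.uniform(0, 10)),
            float(rng.uniform(0, 10)),
            float(rng.uniform(10, 200)),
        )
        for k in range(n)
    ]
    return sp.Region(units)


def random_tally(rng: np.random.Generator) -> sp.DetectionTally:
    """Random valid detection tally for formula cross-checks."""
    s = int(rng.integers(1, 9))
    L = int(rng.integers(s, 31))
    tally = sp.DetectionTally(true_cluster_size=s, max_size=L)
    for _ in range(int(rng.integers(1, 12))):
        l = int(rng.integers(1, L + 1))
        s_star = int(rng.integers(0, min(l, s) + 1))
        for _ in range(int(rng.integers(1, 5))):
            tally.add((l, s_star))
    for _ in range(int(rng.integers(0, 5))):
        tally.add(sp.power.NOT_REJECTED if rng.random() < 0.7 else sp.power.OVERSIZE)
    tally.validate()
    return tally
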