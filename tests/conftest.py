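import numpy as np
import pytest

from ppdscore import cohort
from ppdscore.reference import load_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    return load_reference_cohort()


@pytest.fixture(scope="session")
def reference_trajectories(reference_cohort):
    return cohort.trajectories_from_means(reference_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_disc(size=256, radius=100, level=0.8, background=0.0):
    """Analytically drawn bright disc on a dark background."""
    gray = np.full((size, size), background, dtype=float)
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    gray[(yy - c) ** 2 + (xx - c) ** 2 <= radius**2] = level
    return gray
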