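import numpy as np
import pytest

from plexseg.grids import ImageVolume, LabelMask
from plexseg.phantom import PhantomSpec, make_cohort, make_phantom


def random_mask(rng, shape=(16, 16, 16), p=0.2, spacing=(1.0, 1.0, 1.0)):
    aff = np.diag(list(spacing) + [1.0])
    data = (rng.random(shape) < p).astype(np.uint8)
    return LabelMask(data, aff)


def ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) * spacing[a]) ** 2 for a in range(3))
    aff = np.diag(list(spacing) + [1.0])
    return LabelMask((r2 <= radius ** 2).astype(np.uint8), aff)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One quiet phantom with all three sequences, ~2 cm^3 target."""
    spec = PhantomSpec(noise_sd=0.0, age_years=40, sex="F",
                       base_plexus_volume_cm3=1.8, seed=11)
    return make_phantom(spec, sequences=["t1", "t2", "flair"]), spec


@pytest.fixture(scope="session")
def small_cohort():
    """Eight small-grid subjects for pipeline plumbing tests."""
    subjects, table = make_cohort(
        8, age_range=(25.0, 80.0), sequences=["flair"], seed=42,
        grid_shape=(64, 64, 64), ventricle_base_volume_cm3=5.0,
        base_plexus_volume_cm3=1.0)
    return subjects, table
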