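import numpy as np
import pytest

from intracort import CohortConfig, GroupDesign, PhantomSpec, RegionalProfile
from intracort.phantom import make_template_geometry


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        n_subdivisions=2, inner_radius_mm=12.0, thickness_mm=3.0,
        n_regions=4, voxel_size_mm=1.0, grid_shape=(36, 36, 36),
    )


@pytest.fixture(scope="session")
def profile4():
    return RegionalProfile(
        baseline_R={0: 1.25, 1: 1.15, 2: 1.05, 3: 0.96},
        annual_decline_frac={
            "HC": {0: 0.02, 1: 0.02, 2: 0.02, 3: 0.02},
            "mTBI": {0: 0.40, 1: 0.40, 2: 0.40, 3: 0.40},
        },
    )


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    return make_template_geometry(small_spec)


def small_cohort_config(seed=0, n=20, **overrides):
    cfg = CohortConfig(seed=seed)
    hc = GroupDesign(
        n=n, age_mean=75.4, age_sd=7.0, age_min=60.0, age_max=90.0,
        male_fraction=0.53, ge_scanner_fraction=0.875,
        isi_mean=3.3, isi_sd=0.8, isi_min=0.25,
    )
    tbi = GroupDesign(
        n=n, age_mean=43.1, age_sd=17.0, age_min=19.0, age_max=79.0,
        male_fraction=0.63, ge_scanner_fraction=0.0,
        isi_mean=0.5, isi_sd=0.03, isi_min=0.1,
    )
    kwargs = dict(hc=hc, tbi=tbi, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
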