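import warnings

import numpy as np
import pytest

from neurobag.brainage_model import ModelSpec
from neurobag.pipeline import train_normative
from neurobag.synthetic_cohort import CohortConfig, EffectSpec, generate_normative_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small cohort configuration shared by fast unit tests."""
    return CohortConfig(n_subjects=60, n_regions=8, voxels_per_region=5,
                        seed=5, region_seed=3)


@pytest.fixture(scope="session")
def tiny_normative(tiny_cfg):
    return generate_normative_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def small_trained():
    """A trained model set on a small cohort, reused across model/BAG tests."""
    cfg = CohortConfig(n_subjects=200, n_regions=16, voxels_per_region=6,
                       seed=5, region_seed=3)
    bundle = generate_normative_cohort(cfg)
    spec = ModelSpec(c_grid=(10.0, 100.0), gamma_grid=(1e-2, 1e-1),
                     outer_folds=5, inner_folds=3, seed=0)
    rspec = ModelSpec(c_grid=(10.0,), gamma_grid=None,
                      outer_folds=5, inner_folds=3, seed=0)
    norm = train_normative(bundle, spec=spec, regional_spec=rspec)
    return cfg, bundle, norm
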