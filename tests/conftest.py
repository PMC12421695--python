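import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from decnef.io_formats import FixtureBundle, make_fixtures
from decnef.schedule import AcquisitionParams, RunKind, build_schedule


@pytest.fixture(scope="session")
def fixtures() -> FixtureBundle:
    return make_fixtures(seed=1234)


@pytest.fixture(scope="session")
def small_params() -> AcquisitionParams:
    return AcquisitionParams(n_voxels=20)


@pytest.fixture(scope="session")
def regulation_schedule(small_params):
    return build_schedule(RunKind.REGULATION, small_params, 1)


@pytest.fixture(scope="session")
def task_schedule(small_params):
    return build_schedule(RunKind.DECODER_TRAINING, small_params, 0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
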