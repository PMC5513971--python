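import numpy as np
import pytest

from landmark_homing import (
    LandmarkConfiguration,
    Point2D,
    RidgeParams,
    default_grid_spec,
    exp1_configuration,
)


@pytest.fixture
def gaussian_params():
    return RidgeParams(ridge_radius=6.0, sigma_center=1.0, variant="gaussian")


@pytest.fixture
def mixture_params():
    return RidgeParams(ridge_radius=6.0, sigma_center=1.0, variant="mixture")


@pytest.fixture
def visual_1lm():
    return exp1_configuration("visual", 1)


@pytest.fixture
def visual_3lm():
    return exp1_configuration("visual", 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
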