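import numpy as np
import pytest
from hypothesis import settings

from svdmap import ModelSpec, build_model_map, decompose

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Desk-scale geometry used by the fast unit tests: same shapes as the default
# phantoms, shrunk to a 41 x 41 grid so SVDs take milliseconds.
SMALL_GEOMETRY = dict(
    grid_size=41,
    circle1_radius=15.0,
    circle2_radius=8.0,
    radial_halfwidth_rect=2.0,
    radial_fwhm_lorentz=4.0,
)


def small_spec(kind: str, **overrides) -> ModelSpec:
    params = {**SMALL_GEOMETRY, **overrides}
    return ModelSpec(kind=kind, **params)


@pytest.fixture(scope="session")
def distinct_small():
    return build_model_map(small_spec("distinct"))


@pytest.fixture(scope="session")
def distinct_small_svd(distinct_small):
    return decompose(distinct_small)


@pytest.fixture(scope="session")
def overlapping_small():
    return build_model_map(small_spec("overlapping"))


@pytest.fixture(scope="session")
def on_top_small():
    return build_model_map(small_spec("on_top"))


@pytest.fixture(scope="session")
def distinct_default():
    """The full-size noiseless 'distinct' phantom (101 x 101)."""
    return build_model_map(ModelSpec(kind="distinct"))


@pytest.fixture(scope="session")
def distinct_default_svd(distinct_default):
    return decompose(distinct_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
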