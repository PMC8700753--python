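import numpy as np
import pytest

from capfuse import RigidTransform
from capfuse.phantom import (PhantomConfig, angular_extent_for_extents,
                             generate_phantom)
from capfuse.pipeline import PipelineParams, run_case

# phantom generation is the expensive step; cases are cached per config key
_CASE_CACHE = {}


def make_case(key: str, **kw):
    if key not in _CASE_CACHE:
        _CASE_CACHE[key] = generate_phantom(PhantomConfig(**kw))
    return _CASE_CACHE[key]


def config_with_extents(vertical_mm, horizontal_mm, **kw):
    cfg = PhantomConfig(**kw)
    av, ah = angular_extent_for_extents(vertical_mm, horizontal_mm, cfg)
    return PhantomConfig(**{**cfg.__dict__, "lesion_angular_extent": (av, ah)})


@pytest.fixture(scope="session")
def true_transform():
    return RigidTransform.from_axis_angle((0.3, 1.0, 0.5), 12.0, (4.0, -2.0, 3.0))


@pytest.fixture(scope="session")
def lesion_case(true_transform):
    """Unstable lesion: radial fissure + protrusion + SSB + sclerosis,
    14 x 12 mm footprint, modest acquisition noise."""
    if "lesion" not in _CASE_CACHE:
        cfg = config_with_extents(
            14.0, 12.0, fissure_enabled=True, protrusion_height_mm=1.5,
            ssb_enabled=True, sclerosis_enabled=True, noise_sd=2.0, seed=5,
            true_transform=true_transform)
        _CASE_CACHE["lesion"] = generate_phantom(cfg)
    return _CASE_CACHE["lesion"]


@pytest.fixture(scope="session")
def lesion_result(lesion_case):
    return run_case(lesion_case, PipelineParams(seed=5))


@pytest.fixture(scope="session")
def clean_case():
    """No lesion, no noise, identity inter-modality transform."""
    return make_case("clean", noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def defect_case():
    return make_case("defect", defect_enabled=True, ssb_enabled=True,
                     noise_sd=2.0, seed=11)
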