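import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from savseg.scenes import ClassSpec, SceneSpec, generate_scene, three_class_spec


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic 128x128 three-class scene shared across read-only tests."""
    return generate_scene(three_class_spec(128, 128), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def four_class_spec():
    return SceneSpec(256, 256, (
        ClassSpec(0, "bg", 0.70, base_color=(170, 150, 110), is_background=True),
        ClassSpec(1, "a", 0.15, base_color=(60, 110, 50), patch_area_mean=900.0),
        ClassSpec(2, "b", 0.10, base_color=(120, 60, 40), patch_area_mean=700.0),
        ClassSpec(3, "c", 0.05, base_color=(40, 80, 90), patch_area_mean=500.0),
    ))
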