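import numpy as np
import pytest

from endoguide.guidance import plan_scene
from endoguide.scene import build_scene


@pytest.fixture(scope="session")
def porcine_scene():
    return build_scene("porcine")


@pytest.fixture(scope="session")
def porcine_plan(porcine_scene):
    return plan_scene(porcine_scene)


@pytest.fixture(scope="session")
def cadaver_scene():
    return build_scene("cadaver")


@pytest.fixture(scope="session")
def cadaver_plan(cadaver_scene):
    return plan_scene(cadaver_scene)


@pytest.fixture(scope="session")
def anthro_scene():
    return build_scene("anthro")


@pytest.fixture(scope="session")
def anthro_plan(anthro_scene):
    return plan_scene(anthro_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
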