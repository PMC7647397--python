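import numpy as np
import pytest

import widefield_mc as wm


@pytest.fixture(scope="session")
def window_scene():
    return wm.build_scene("window")


@pytest.fixture(scope="session")
def objective():
    return wm.TL2X_SAP


@pytest.fixture(scope="session")
def small_illumination(window_scene, objective):
    """Shared 5e4-photon illumination run through the cranial window."""
    return wm.run_illumination(window_scene, objective, 50_000, seed=101)


@pytest.fixture(scope="session")
def small_collection_surface(window_scene, objective):
    """Shared 2e5-photon collection run, point source at the surface."""
    return wm.run_collection_from_point(window_scene, 0.0, objective, 200_000, seed=202)


@pytest.fixture(scope="session")
def small_collection_1mm(window_scene, objective):
    return wm.run_collection_from_point(window_scene, 1.0, objective, 200_000, seed=203)


@pytest.fixture(scope="session")
def vacuum_scene():
    """Non-interacting tissue: photons travel ballistically."""
    props = wm.OpticalProperties(0.0, 0.0, 0.0)
    return wm.build_scene("window").with_grey_matter(480, props).with_grey_matter(560, props)
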