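import warnings

import pytest

from synaptomorph.synthgen import SceneSpec, VesicleParams, make_scene, slice_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic bouton scene, shared read-only across tests."""
    scene, truth = make_scene(SceneSpec(seed=1))
    return scene, truth


@pytest.fixture(scope="session")
def default_stack(default_scene):
    scene, truth = default_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = slice_scene(scene, truth=truth)
    return stack, truth, scene


@pytest.fixture()
def small_spec():
    """A light-weight scene spec for round-trip and CLI tests."""
    return SceneSpec(
        seed=3,
        vesicles=VesicleParams(n_total=40),
        n_dcv=2,
        n_docked=1,
    )
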