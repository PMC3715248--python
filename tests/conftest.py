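import numpy as np
import pytest

from vineseg import evaluation as ev
from vineseg import pipeline as pl
from vineseg import synthscene as ss


@pytest.fixture(scope="session")
def signatures():
    return ss.default_signatures()


@pytest.fixture(scope="session")
def default_scene(signatures):
    """The default synthetic scene (seed 0) with ground truth."""
    return ss.generate_scene(ss.SceneSpec(), signatures)


@pytest.fixture(scope="session")
def classified_default_scene(default_scene):
    """Sequential classification of the default scene plus its report."""
    labels, stages = pl.classify_scene(default_scene)
    report = ev.scene_report(labels, default_scene.truth, default_scene.scene_id)
    return default_scene, labels, stages, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
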