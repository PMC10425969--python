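import numpy as np
import pytest

from mpquant import (
    SceneSpec,
    render_bead_image,
    process_image,
)


@pytest.fixture(scope="session")
def bead_scene():
    """One default 50-bead scene (90-106 um beads at 2 um/px) with truth."""
    spec = SceneSpec(seed=1)
    img, truth = render_bead_image(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def bead_table(bead_scene):
    """The processed particle table of the default bead scene."""
    _, img, _ = bead_scene
    return process_image(img, "scene-1")


@pytest.fixture(scope="session")
def random_histograms():
    """100 seeded random 256-bin histograms of mixed shapes for threshold tests."""
    rng = np.random.default_rng(2024)
    hists = []
    for _ in range(100):
        h = np.zeros(256, dtype=np.int64)
        for _ in range(rng.integers(1, 4)):
            m = rng.integers(5, 251)
            s = rng.uniform(2, 40)
            x = np.arange(256)
            h += np.round(
                rng.integers(100, 5000)
                * np.exp(-0.5 * ((x - m) / s) ** 2)
            ).astype(np.int64)
        h += rng.integers(0, 5, size=256)
        hists.append(h)
    return hists
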