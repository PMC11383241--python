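import numpy as np
import pytest

from floracount import synth
from floracount.voc import AnnotatedImage, Annotation, Box


@pytest.fixture
def three_species():
    return synth.default_species(3)


@pytest.fixture
def sparse_scene(three_species):
    """Non-overlapping fixed-count scene: ground truth is easy to reason about."""
    cfg = synth.SceneConfig(
        width=320,
        height=256,
        species=three_species,
        abundance=synth.FixedAbundance(
            {"species_00": 4, "species_01": 3, "species_02": 2}
        ),
        overlap_allowed=False,
        clutter_rate=2.0,
        seed=11,
    )
    return synth.generate_scene(cfg)


def random_layout(rng: np.random.Generator, width=400, height=300, n_boxes=12):
    """A random annotated image without pixels, for geometry tests."""
    anns = []
    for k in range(n_boxes):
        w = int(rng.integers(5, 60))
        h = int(rng.integers(5, 60))
        x0 = int(rng.integers(0, width - w))
        y0 = int(rng.integers(0, height - h))
        label = f"sp{int(rng.integers(3))}"
        anns.append(Annotation(label, Box(x0, y0, x0 + w, y0 + h), f"a{k}"))
    return AnnotatedImage("layout", width, height, anns)
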