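import numpy as np
import pytest

from fibis import segment, synth

REP_RATE = 80e6
PERIOD_NS = 12.5


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fibis_config():
    return segment.FibisConfig(pixel_size_um=0.2)


@pytest.fixture(scope="session")
def ten_object_clean_scene():
    """A designed clean scene: ten well-separated in-range objects of
    uniform brightness on a grid, no drift, no stripes."""
    objs = []
    positions = [(r, c) for r in (45, 105, 165, 225) for c in (45, 105, 165, 225)]
    for i in range(10):
        cy, cx = positions[i]
        objs.append(
            synth.SceneObject(
                shape="capsule" if i % 2 else "ellipse",
                center_px=(float(cy), float(cx)),
                angle_rad=0.3 * i,
                length_um=1.2 + 0.25 * i,
                width_um=0.7,
                true_bound_fraction=0.5,
                peak_photon_rate=60.0,
            )
        )
    return synth.make_scene("clean", seed=11, objects=objs)


@pytest.fixture(scope="session")
def ten_object_clean(ten_object_clean_scene):
    return synth.render_stack(ten_object_clean_scene, render_decay=False)
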