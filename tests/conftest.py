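import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cortexflat as cf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_RIBBON = (
    (120.0, 100.0),
    (450.0, 140.0),
    (800.0, 300.0),
    (1050.0, 520.0),
    (1130.0, 800.0),
)


@pytest.fixture
def small_params():
    """A small section that still satisfies the classification margins."""
    return cf.SynthParams(
        image_width=1200,
        image_height=900,
        n_cells=6,
        n_tracer_positive=4,
        ribbon_control_points=SMALL_RIBBON,
        ribbon_halfwidth=170.0,
        seed=11,
    )


@pytest.fixture
def small_section(small_params):
    return cf.generate_section(small_params)


@pytest.fixture
def straight_line():
    """Horizontal unit-spacing reference line with anchor at the origin."""
    verts = np.column_stack([np.arange(0.0, 101.0), np.zeros(101)])
    return cf.ReferenceLine(verts, cingulum_anchor=0, pixel_size=1.0)
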