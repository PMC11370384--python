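import numpy as np
import pytest

from hippodev.protocol import make_protocol
from hippodev.synthgen import make_slab_phantom


@pytest.fixture(scope="session")
def protocol():
    """The 6-shell study protocol (254 volumes)."""
    return make_protocol(seed=1)


@pytest.fixture(scope="session")
def curved_phantom():
    return make_slab_phantom()


@pytest.fixture(scope="session")
def straight_phantom():
    return make_slab_phantom(arc_deg=0.0)


@pytest.fixture(scope="session")
def curved_coords(curved_phantom):
    from hippodev.hippogeom import solve_phantom_coordinates

    return solve_phantom_coordinates(curved_phantom)


@pytest.fixture(scope="session")
def straight_coords(straight_phantom):
    from hippodev.hippogeom import solve_phantom_coordinates

    return solve_phantom_coordinates(straight_phantom)


@pytest.fixture(scope="session")
def small_mesh():
    from hippodev.mesh import build_template_mesh

    return build_template_mesh(n_ap=40, n_pd=20, n_apex=0)
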