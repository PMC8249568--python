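import numpy as np
import pytest
from hypothesis import settings

import sws4d as s

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def straight_frame(n=51, length=50.0, radius=1.5, phase="diastasis"):
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0.0, length, n)])
    return s.VesselFrame(
        centerline=s.Centerline(points=pts),
        ring_radius=np.full(n, radius),
        phase=phase,
    )


def cylinder_grid(L=11, C=16, radius=1.5, length=10.0):
    z = np.linspace(0.0, length, L)
    theta = 2.0 * np.pi * np.arange(C) / C
    nodes = np.empty((L, C, 3))
    nodes[..., 0] = radius * np.cos(theta)[None, :]
    nodes[..., 1] = radius * np.sin(theta)[None, :]
    nodes[..., 2] = z[:, None]
    return nodes


@pytest.fixture(scope="session")
def materials():
    return s.default_materials()


@pytest.fixture(scope="session")
def stenotic_vessel():
    return s.make_stenosis_model(s.PlaqueSpec(composition="fibrous", burden_target=0.509))


@pytest.fixture(scope="session")
def stenotic_mesh(stenotic_vessel):
    return s.build_structured_mesh(stenotic_vessel.lumen, L=51, C=16)
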