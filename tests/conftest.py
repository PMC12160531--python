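import numpy as np
import pytest

from valvemetrics.synthetic_data import GeneratorSpec
from valvemetrics.valve_geometry import SurfaceMesh, build_leaflet, default_design
from valvemetrics.waveforms import UNIT_FLOW, Waveform


def half_sine_flow(peak=400.0, duration=0.3, period=1.0, n=512):
    """Half-sine systolic lobe starting at t=0, zero diastole."""
    t = np.linspace(0.0, period, n, endpoint=False)
    v = np.where(t < duration, peak * np.sin(np.pi * np.clip(t, 0, duration) / duration), 0.0)
    return Waveform(t, v, period, UNIT_FLOW)


def rect_pulse_flow(level=300.0, t_on=0.1, t_off=0.4, period=1.0, n=1001):
    """Rectangular pulse with sample edges exactly at t_on and t_off."""
    t = np.linspace(0.0, period, n)
    v = np.where((t >= t_on) & (t <= t_off), level, 0.0)
    return Waveform(t, v, period, UNIT_FLOW)


@pytest.fixture
def gen_spec():
    return GeneratorSpec(seed=42)


@pytest.fixture(scope="session")
def leaflet_mesh():
    return build_leaflet(default_design(), resolution=(16, 16))


@pytest.fixture
def two_face_mesh():
    """Two equal-area right triangles sharing an edge, labelled A and B."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(verts, tris, face_labels=np.array(["A", "B"], dtype=object))
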