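"""Shared fixtures: generated phantoms and hand-built lung geometries."""

from __future__ import annotations

import numpy as np
import pytest

from ppolung import PhantomConfig, generate_thorax_phantom
from ppolung.traces import FissureTraceSet, TracePolyline


@pytest.fixture(scope="session")
def default_phantom():
    """One 64³ phantom with default (physiologic) settings, shared read-only."""
    config = PhantomConfig(seed=11)
    ct, spect, truth = generate_thorax_phantom(config)
    return config, ct, spect, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Phantom with no gravity gradient, lesions, or vessels: geometry only."""
    config = PhantomConfig(seed=5, gravity_gradient=0.0, vessels=False)
    ct, spect, truth = generate_thorax_phantom(config)
    return config, ct, spect, truth


def make_box_lungs(shape=(24, 24, 24)):
    """Two rectangular 'lungs' clear of the volume border: right spans
    x 3..8, left x 15..20, both y 6..17, z 4..19."""
    lung = np.zeros(shape, dtype=np.uint8)
    lung[4:20, 6:18, 3:9] = 1
    lung[4:20, 6:18, 15:21] = 1
    return lung


def const_y_polyline(z, above, below, y, x0=-1.0, x1=24.0, above_anterior=True):
    """A straight constant-y trace; vertex order encodes which side is
    lobe_above (see traces module)."""
    if above_anterior:
        vertices = [[x1, y], [x0, y]]
    else:
        vertices = [[x0, y], [x1, y]]
    return TracePolyline(z, above, below, np.asarray(vertices, dtype=float))


def box_traces(z_slices, y_left=12.5, y_obl=12.5, y_hor=9.5):
    """Complete trace set for the box lungs with constant-y boundaries."""
    traces = FissureTraceSet()
    for z in z_slices:
        traces.add(const_y_polyline(z, "LUL", "LLL", y_left))
        traces.add(const_y_polyline(z, "RUL", "RLL", y_obl))
        traces.add(const_y_polyline(z, "RUL", "RML", y_hor, above_anterior=False))
    return traces
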