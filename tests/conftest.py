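"""Shared phantom fixtures.

Everything is generated at test time; session scope keeps the rendering
cost of the larger cine loops to a single run per suite.
"""

import numpy as np
import pytest

from cavatrack.phantom import (
    PhantomSpec,
    PressureDrivers,
    PressureVolumeCurve,
    generate_long_axis,
    generate_short_axis,
    preset,
)

FPS = 30.0


@pytest.fixture(scope="session")
def curve():
    return PressureVolumeCurve()


@pytest.fixture(scope="session")
def static_long():
    """Noise-free static long-axis phantom: no drivers, no speckle."""
    spec = PhantomSpec(view="long_axis", shape=(128, 256), D0=40.0,
                       psf_sigma=1.0, seed=0)
    drivers = PressureDrivers(A_card=0.0, A_resp=0.0)
    video, truth = generate_long_axis(spec, PressureVolumeCurve(), drivers,
                                      40, fps=FPS)
    return spec, video, truth


@pytest.fixture(scope="session")
def dynamic_long():
    """Default speckled dynamic long-axis phantom, 20 s."""
    spec, curve, drivers = preset("default", "long_axis", seed=3)
    video, truth = generate_long_axis(spec, curve, drivers, 600, fps=FPS)
    return spec, video, truth


@pytest.fixture(scope="session")
def static_short():
    """Noise-free static circular cross-section."""
    spec = PhantomSpec(view="short_axis", shape=(128, 128), D0=60.0,
                       psf_sigma=1.0, seed=0)
    drivers = PressureDrivers(A_card=0.0, A_resp=0.0)
    video, truth = generate_short_axis(spec, PressureVolumeCurve(), drivers,
                                       30, fps=FPS)
    return spec, video, truth


@pytest.fixture(scope="session")
def dynamic_short():
    """Default speckled pulsating short-axis phantom, 20 s."""
    spec, curve, drivers = preset("default", "short_axis", seed=3)
    video, truth = generate_short_axis(spec, curve, drivers, 600, fps=FPS)
    return spec, video, truth


def two_sinusoid_series(fps=30.0, seconds=60.0):
    """The bench series 40 + 3 sin(2π·0.25 t) + 0.8 sin(2π·1.2 t)."""
    t = np.arange(int(seconds * fps)) / fps
    resp = 3.0 * np.sin(2 * np.pi * 0.25 * t)
    card = 0.8 * np.sin(2 * np.pi * 1.2 * t)
    return 40.0 + resp + card, 40.0 + resp, card
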