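"""Shared fixtures.

The expensive multi-animal study simulations are session-scoped so the
acceptance-level tests (dilation recovery, null preservation, baseline
diametry, tracking) share one run each.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from octavasc.phantom import (
    PhantomSpec,
    high_intensity_scenario,
    low_intensity_scenario,
    sham_scenario,
)
from octavasc.pipeline import run_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _quiet_run_study(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(*args, **kwargs)


@pytest.fixture(scope="session")
def low_study():
    """10-animal study at the low-intensity effect (small vessels x1.17)."""
    return _quiet_run_study(PhantomSpec(), low_intensity_scenario(10), seed=1)


@pytest.fixture(scope="session")
def high_study():
    """10-animal study at the high-intensity effect (small vessels x1.27)."""
    return _quiet_run_study(PhantomSpec(), high_intensity_scenario(10), seed=2)


@pytest.fixture(scope="session")
def sham_study():
    """3-animal sham study: no effect anywhere."""
    return _quiet_run_study(PhantomSpec(), sham_scenario(3), seed=3)


@pytest.fixture
def tube_image():
    """Noise-free en-face image with one straight horizontal Gaussian tube."""
    from octavasc.volume_prep import EnFaceImage

    ny, nx, px = 80, 120, 2.0
    d_um = 10.0
    y0 = 40.5
    yy = (np.arange(ny)[:, None] - y0) * px
    img = 0.6 * np.exp(-4.0 * np.log(2.0) * yy**2 / d_um**2) * np.ones((1, nx))
    return EnFaceImage(pixels=img.astype(np.float32), depth_range_um=(0, 400), pixel_um=px), d_um
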