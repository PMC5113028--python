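import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vibroglove import (
    BandGrid,
    PointMeasurement,
    ToolSpectrum,
    TransmissibilitySpectrum,
    make_band_grid,
)


@pytest.fixture(scope="session")
def full_grid() -> BandGrid:
    return make_band_grid(6.3, 1250.0)


@pytest.fixture(scope="session")
def assess_grid() -> BandGrid:
    return make_band_grid(6.3, 500.0)


@pytest.fixture(scope="session")
def measured_grid() -> BandGrid:
    """The 16-500 Hz range the laboratory rig can drive."""
    return make_band_grid(16.0, 500.0)


def make_spectrum(grid, values, glove="g1", location="fingertip", direction="y"):
    return TransmissibilitySpectrum(
        glove_id=glove, location=location, direction=direction,
        grid=grid, values=np.asarray(values, dtype=float),
    )


def make_tool(grid, ax, ay, az, tool_id="tool"):
    return ToolSpectrum(tool_id=tool_id, grid=grid, ax=ax, ay=ay, az=az)


def random_spectrum(rng, grid, lo=0.3, hi=1.8, **tags):
    return make_spectrum(grid, rng.uniform(lo, hi, len(grid)), **tags)


def random_tool(rng, grid, tool_id="tool"):
    shape = (len(grid),)
    return make_tool(
        grid,
        ax=rng.uniform(0.0, 20.0, shape),
        ay=rng.uniform(0.0, 20.0, shape),
        az=rng.uniform(0.0, 20.0, shape),
        tool_id=tool_id,
    )


def make_measurement(grid, response, excitation, **kw):
    defaults = dict(
        subject_id="S1", glove_id="g1", finger="index", area=1, point_id="P1",
        grip_n=30.0, push_n=50.0, direction="y",
    )
    defaults.update(kw)
    return PointMeasurement(
        grid=grid, response=np.asarray(response, float),
        excitation=np.asarray(excitation, float), **defaults,
    )
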