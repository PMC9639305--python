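import dataclasses

import numpy as np
import pytest

from nsdremote import myogeometry as geo
from nsdremote.phantom import PhantomSpec, generate_slice


def make_spec(**overrides) -> PhantomSpec:
    """Noiseless bias-free baseline spec; override freely."""
    defaults = dict(noise_model="none", remote_sd=0.0, infarct_sd=0.0, bias_amplitude=0.0)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def noiseless_slice():
    return generate_slice(make_spec())


@pytest.fixture
def noiseless_prep(noiseless_slice):
    """Polar map + a mid-remote 45-degree ROI for the noiseless slice."""
    sl = noiseless_slice
    polar = geo.polar_parameterize(sl.endo_contour, sl.epi_contour, sl.myo_mask)
    roi = geo.sector_roi(polar, 180.0, 45.0, 0.15)
    return sl, polar, roi


def replace_spec(spec: PhantomSpec, **kw) -> PhantomSpec:
    return dataclasses.replace(spec, **kw)


def random_mask(rng: np.random.Generator, shape, density: float) -> np.ndarray:
    return rng.random(shape) < density
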