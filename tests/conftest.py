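"""Shared fixtures: phantoms and analyzed pipelines reused across modules."""

import numpy as np
import pytest

from larynxcad import phantom, pipeline
from larynxcad.config import RunConfig


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def noiseless_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(noise_sigma=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return phantom.generate_image(noiseless_spec)


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_phantom, run_config):
    """Full analysis (compensate/enhance/segment/features) of the default noiseless phantom."""
    img, gt = noiseless_phantom
    result = pipeline.analyze_image(img, run_config)
    return img, gt, result


@pytest.fixture(scope="session")
def polyp_phantom():
    spec = phantom.PhantomSpec(
        noise_sigma=0.0,
        blur_sigma=0.0,
        lesion=phantom.LesionSpec(label="polyp", side="left", protrusion_radius=12.0, base_width=16.0),
    )
    return phantom.generate_image(spec)


@pytest.fixture(scope="session")
def analyzed_polyp(polyp_phantom, run_config):
    img, gt = polyp_phantom
    result = pipeline.analyze_image(img, run_config)
    return img, gt, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
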