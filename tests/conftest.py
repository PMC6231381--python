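"""Shared fixtures: study phantoms and cached end-to-end pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

import vesselfc as v


@pytest.fixture(scope="session")
def phantom_clean():
    """Default high-contrast study phantom, no noise."""
    spec = v.VesselPhantomSpec()
    image, gold, liver = v.generate_phantom(spec)
    return {"spec": spec, "image": image, "gold": gold, "liver": liver}


@pytest.fixture(scope="session")
def phantom_noisy():
    """Same tree with sigma^2 = 60 Gaussian white noise."""
    spec = v.VesselPhantomSpec(noise_variance=60.0)
    image, gold, liver = v.generate_phantom(spec)
    return {"spec": spec, "image": image, "gold": gold, "liver": liver}


@pytest.fixture(scope="session")
def run_improved(phantom_clean):
    mask, report = v.run_pipeline(
        v.PipelineConfig(), phantom_clean["image"], phantom_clean["liver"]
    )
    return {"mask": mask, "report": report}


@pytest.fixture(scope="session")
def run_improved_noisy(phantom_noisy):
    mask, report = v.run_pipeline(
        v.PipelineConfig(), phantom_noisy["image"], phantom_noisy["liver"]
    )
    return {"mask": mask, "report": report}


@pytest.fixture(scope="session")
def run_traditional(phantom_clean):
    mask, report = v.run_pipeline(
        v.PipelineConfig(mode="traditional_fc"),
        phantom_clean["image"],
        phantom_clean["liver"],
    )
    return {"mask": mask, "report": report}


@pytest.fixture(scope="session")
def scene_state(phantom_clean):
    """Pipeline state through the fuzzy scene, for threshold sweeps."""
    return v.run_to_scene(
        v.PipelineConfig(), phantom_clean["image"], phantom_clean["liver"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
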