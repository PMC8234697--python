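from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ccfd.image_io import EnFaceImage

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ccfd.synthetic import SceneParams, generate_scene


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210616)


@pytest.fixture
def random_flow_image(rng) -> EnFaceImage:
    return EnFaceImage(rng.random((32, 32)), modality="flow", eye_id="rand")


@pytest.fixture
def small_scene():
    """A 128-px noisy scene with drusen shadows (scaled-down drusen load)."""
    params = SceneParams(size_px=128, n_drusen=2, drusen_radius_px=(10.0, 20.0), seed=42)
    return generate_scene(params)


def uniform_image(level: float, shape=(32, 32), modality="flow") -> EnFaceImage:
    return EnFaceImage(np.full(shape, level), modality=modality)
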