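"""Shared fixtures: small, fast synthetic scenes with known ground truth."""

import numpy as np
import pytest

from laminq import OpticsConfig, SceneConfig, build_lamina_scene, render_image


@pytest.fixture(scope="session")
def small_mid_scene():
    """Compact mid-plane scene (2.0 x 1.5 um nucleus) for fast rendering."""
    return SceneConfig(view="mid_plane", nucleus_semi_axes=(2.0, 1.5), margin_um=0.9)


@pytest.fixture(scope="session")
def small_mid_gt(small_mid_scene):
    return build_lamina_scene(small_mid_scene, seed=7)


@pytest.fixture(scope="session")
def sted_noiseless_mid(small_mid_gt):
    return render_image(small_mid_gt, OpticsConfig(modality="sted"), noiseless=True)


@pytest.fixture(scope="session")
def confocal_noiseless_mid(small_mid_gt):
    return render_image(small_mid_gt, OpticsConfig(modality="confocal"), noiseless=True)


@pytest.fixture
def top_scene_factory():
    def make(rho: float, seed: int = 0, **kwargs) -> tuple:
        cfg = SceneConfig(
            view="top", nucleus_semi_axes=(3.0, 2.2), shared_fraction=rho, **kwargs
        )
        return cfg, build_lamina_scene(cfg, seed=seed)

    return make
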