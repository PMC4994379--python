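import pytest

import fireflux as ff


@pytest.fixture(scope="session")
def clean_scene():
    """Default-condition scene, zero reflectance noise, fixed seed."""
    cfg = ff.LandscapeConfig(grid_rows=120, grid_cols=120,
                             reflectance_noise_sd=0.0, seed=3)
    return ff.generate_scene(cfg)


@pytest.fixture(scope="session")
def mapped_burn(clean_scene):
    """Burn map recovered from the clean scene's reflectance stack."""
    return ff.map_burn_scars(clean_scene.reflectance_by_month)


@pytest.fixture(scope="session")
def loss_model():
    return ff.LossModel(alpha=0.7084, alpha_sd=0.034)
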