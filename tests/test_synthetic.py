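"""Synthetic-landscape generator: calibration, determinism, ground truth."""

import numpy as np
import pytest

import fireflux as ff
from fireflux.burnmap import DEFAULT_ENDMEMBERS, unmix
from fireflux.grids import Raster
from fireflux.synthetic import (
    BURNED_FRACTIONS,
    LandscapeConfig,
    generate_reflectance,
    truth_fraction_image,
)


def small_config(**kw):
    defaults = dict(grid_rows=80, grid_cols=80, reflectance_noise_sd=0.0, seed=7)
    defaults.update(kw)
    return LandscapeConfig(**defaults)


class TestLandcover:
    def test_single_class_uniform(self):
        cfg = small_config(class_proportions={1: 1.0})
        lc = ff.generate_landcover(cfg)
        assert np.all(lc.data == 1)

    def test_published_proportions_realized_within_2pp(self):
        # old-growth forest share 289,358/899,645 = 0.3216 on a 400x400 grid
        cfg = LandscapeConfig(grid_rows=400, grid_cols=400, seed=1)
        lc = ff.generate_landcover(cfg)
        realized = {c: (lc.data == c).mean() for c in cfg.class_proportions}
        assert 0.30 <= realized[1] <= 0.34
        for c, want in cfg.class_proportions.items():
            assert abs(realized[c] - want) <= 0.02, (c, realized[c], want)

    def test_deterministic_under_seed(self):
        a = ff.generate_landcover(small_config())
        b = ff.generate_landcover(small_config())
        assert np.array_equal(a.data, b.data)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            ff.generate_landcover(small_config(class_proportions={1: 0.6, 2: 0.6}))
        with pytest.raises(ValueError):
            ff.generate_landcover(small_config(grid_rows=0))


class TestBiomass:
    def test_zero_sd_gives_class_means(self):
        cfg = small_config()
        cfg.class_biomass_sd = {c: 0.0 for c in cfg.class_biomass_sd}
        lc = ff.generate_landcover(cfg)
        biomass, error = ff.generate_biomass(lc, cfg)
        for code in np.unique(lc.data):
            want = cfg.class_biomass_mean[int(code)]
            assert np.all(biomass.data[lc.data == code] == want)
        assert np.all(error.data == 0)

    def test_sample_mean_matches_class_parameters(self):
        # forest: mean 176.3, sd 34.63; tolerance 3 standard errors at n>=1e5
        cfg = LandscapeConfig(grid_rows=330, grid_cols=330,
                              class_proportions={1: 1.0}, seed=2)
        lc = ff.generate_landcover(cfg)
        biomass, _ = ff.generate_biomass(lc, cfg)
        n = biomass.data.size
        assert n >= 1e5
        assert abs(biomass.data.mean() - 176.3) < 3 * 34.63 / np.sqrt(n)

    def test_truncation_at_zero(self):
        cfg = small_config()
        cfg.class_biomass_mean = {c: 5.0 for c in cfg.class_biomass_mean}
        cfg.class_biomass_sd = {c: 50.0 for c in cfg.class_biomass_sd}
        lc = ff.generate_landcover(cfg)
        biomass, _ = ff.generate_biomass(lc, cfg)
        assert biomass.data.min() >= 0.0

    def test_unknown_class_rejected(self):
        cfg = small_config()
        lc = ff.generate_landcover(cfg)
        cfg2 = small_config()
        cfg2.class_biomass_mean = {99: 1.0}
        with pytest.raises(KeyError):
            ff.generate_biomass(lc, cfg2)


class TestBurns:
    def test_zero_fractions_empty_mask(self):
        cfg = small_config()
        cfg.burn_fraction_by_class = {c: 0.0 for c in cfg.burn_fraction_by_class}
        lc = ff.generate_landcover(cfg)
        burn, patches = ff.generate_burns(lc, cfg)
        assert not burn.burned.any() and not patches

    def test_forest_burned_fraction_within_20pct_relative(self):
        cfg = LandscapeConfig(grid_rows=300, grid_cols=300, seed=4)
        cfg.burn_fraction_by_class = {c: (0.045 if c == 1 else 0.0)
                                      for c in cfg.burn_fraction_by_class}
        lc = ff.generate_landcover(cfg)
        burn, _ = ff.generate_burns(lc, cfg)
        forest = lc.data == 1
        realized = burn.burned[forest].sum() / forest.sum()
        assert 0.036 <= realized <= 0.054

    def test_all_patches_at_least_min_size(self, clean_scene):
        assert all(p.n_px >= clean_scene.config.min_patch_px
                   for p in clean_scene.patches)

    def test_overfull_fraction_rejected(self):
        cfg = small_config()
        lc = ff.generate_landcover(cfg)
        cfg.burn_fraction_by_class = {c: 1.5 for c in cfg.burn_fraction_by_class}
        with pytest.raises(ValueError):
            ff.generate_burns(lc, cfg)

    def test_burn_months_in_fire_season(self, clean_scene):
        months = set(np.unique(clean_scene.truth_burn.month)) - {0}
        assert months <= {6, 7, 8, 9, 10}


class TestReflectance:
    def test_pure_pixel_equals_endmember(self):
        fr = np.zeros((2, 2, 3))
        fr[..., 0] = 1.0  # pure vegetation
        burn = ff.BurnScarMap(np.zeros((2, 2), dtype=np.uint8))
        r = generate_reflectance(fr, burn, month=6)
        assert np.allclose(r.data[0, 0], DEFAULT_ENDMEMBERS.vegetation)

    def test_linearity_of_mixture(self):
        fr = np.zeros((1, 1, 3))
        fr[0, 0] = (0.6, 0.0, 0.4)
        burn = ff.BurnScarMap(np.zeros((1, 1), dtype=np.uint8))
        r = generate_reflectance(fr, burn, month=6)
        want = 0.6 * np.array(DEFAULT_ENDMEMBERS.vegetation) + 0.4 * np.array(
            DEFAULT_ENDMEMBERS.shade
        )
        assert np.allclose(r.data[0, 0], want)

    def test_burned_pixels_get_burn_signature(self, clean_scene):
        month, r = clean_scene.reflectance_by_month[-1]  # October: all burns visible
        burned = clean_scene.truth_burn.burned
        want = np.array(BURNED_FRACTIONS) @ DEFAULT_ENDMEMBERS.matrix().T
        assert np.allclose(r.data[burned], want)

    def test_unmix_roundtrip_recovers_truth_fractions(self, clean_scene):
        fr = truth_fraction_image(clean_scene.landcover, clean_scene.config)
        burn0 = ff.BurnScarMap(np.zeros(fr.shape[:2], dtype=np.uint8))
        r = generate_reflectance(fr, burn0, month=6)
        recovered = unmix(r).fractions
        assert np.max(np.abs(recovered - fr)) < 1e-6


class TestActiveFires:
    def test_zero_rate_empty(self, clean_scene):
        rng = np.random.default_rng(0)
        assert ff.generate_active_fires(clean_scene.truth_burn, clean_scene.patches,
                                        0.0, rng=rng) == []

    def test_negative_rate_rejected(self, clean_scene):
        with pytest.raises(ValueError):
            ff.generate_active_fires(clean_scene.truth_burn, clean_scene.patches, -1.0)

    def test_expected_count_poisson(self, clean_scene):
        rng = np.random.default_rng(1)
        rate = 8.0
        fires = ff.generate_active_fires(clean_scene.truth_burn, clean_scene.patches,
                                         rate, rng=rng)
        expected = rate * len(clean_scene.patches)
        assert abs(len(fires) - expected) <= 3 * np.sqrt(expected)

    def test_high_confidence_fires_all_retained(self, clean_scene):
        rng = np.random.default_rng(2)
        fires = ff.generate_active_fires(
            clean_scene.truth_burn, clean_scene.patches, 3.0,
            confidence_range=(81.0, 100.0), rng=rng,
        )
        kept = ff.filter_fires(fires, clean_scene.truth_burn)
        assert len(kept) == len(fires) > 0


class TestPlotPairs:
    def test_zero_noise_collinear_through_origin(self):
        pairs = ff.generate_plot_pairs(20, true_slope=0.7, x_error_sd=0.0,
                                       y_error_sd=0.0, seed=1)
        for p in pairs:
            assert p.b_after == pytest.approx(0.7 * p.b_initial, rel=1e-12)

    def test_deterministic_under_seed(self):
        a = ff.generate_plot_pairs(30, seed=9)
        b = ff.generate_plot_pairs(30, seed=9)
        assert a == b

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ff.generate_plot_pairs(1)


class TestSceneCoherence:
    def test_all_rasters_share_grid(self, clean_scene):
        s = clean_scene
        shapes = {s.landcover.shape, s.biomass.shape, s.biomass_error.shape,
                  s.truth_burn.shape}
        shapes |= {r.shape for _, r in s.reflectance_by_month}
        assert shapes == {(120, 120)}

    def test_truth_burn_has_high_shade(self, clean_scene):
        # every truth-burned pixel carries a shade fraction above the
        # classification floor in its burn month's image
        month, r = clean_scene.reflectance_by_month[-1]
        shade = unmix(r).shade
        assert shade[clean_scene.truth_burn.burned].min() > 0.5

    def test_scene_determinism(self):
        cfg = small_config()
        a = ff.generate_scene(cfg)
        b = ff.generate_scene(small_config())
        assert np.array_equal(a.landcover.data, b.landcover.data)
        assert np.array_equal(a.biomass.data, b.biomass.data)
        assert np.array_equal(a.truth_burn.month, b.truth_burn.month)
        assert a.fires == b.fires
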