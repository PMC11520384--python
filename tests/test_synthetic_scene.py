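"""Generator contracts: seed determinism, effect recovery, growth, plan size."""

import numpy as np
import pytest

from hsistress import NoiseModel, ScenePlan, generate_scene, generate_study
from hsistress.synthetic_scene import (
    GrowthModel,
    StressEffect,
    coleus_model,
    default_diurnal,
    default_models,
    default_stress,
    generate_scene,
    ratio_from_windows,
    soybean_model,
)

from conftest import SCENE_SHAPE, make_meta


class TestEndmembers:
    def test_soybean_profile_shape(self, axis):
        m = soybean_model(axis)
        wl = axis.wavelengths_nm
        nir = m.endmember[(wl >= 750) & (wl <= 900)]
        assert nir.min() >= 0.4
        # local minimum of the red region falls inside 660-680 nm
        red_region = (wl >= 620) & (wl <= 700)
        min_nm = wl[red_region][np.argmin(m.endmember[red_region])]
        assert 660 <= min_nm <= 680

    def test_coleus_profile_is_reddish(self, axis):
        m = coleus_model(axis)
        wl = axis.wavelengths_nm
        red = m.endmember[(wl >= 600) & (wl <= 700)].mean()
        green = m.endmember[(wl >= 500) & (wl <= 580)].mean()
        assert red > green

    @pytest.mark.parametrize("species", ["soybean", "coleus"])
    def test_endmember_in_unit_interval(self, axis, species):
        m = soybean_model(axis) if species == "soybean" else coleus_model(axis)
        assert np.all(m.endmember >= 0) and np.all(m.endmember <= 1)


class TestEffectDefaults:
    def test_soybean_diurnal_direction(self, axis):
        ratio = default_diurnal("soybean", axis).ratio
        wl = axis.wavelengths_nm
        inside = (wl >= 730) & (wl < 900)
        assert np.all(ratio[~inside] < 1)
        assert np.all(ratio > 0)

    def test_coleus_diurnal_direction(self, axis):
        ratio = default_diurnal("coleus", axis).ratio
        wl = axis.wavelengths_nm
        dark_window = (wl >= 580) & (wl < 670)
        assert np.all(ratio[dark_window] < 1)
        assert np.all(ratio[~dark_window] > 1)

    @pytest.mark.parametrize("species", ["soybean", "coleus"])
    def test_high_departs_more_than_low(self, axis, species):
        eff = default_stress(species, axis)
        assert np.all(
            np.abs(np.log(eff.ratio_high)) >= np.abs(np.log(eff.ratio_low)) - 1e-12
        )

    def test_inconsistent_stress_rejected(self, axis):
        high = np.ones(axis.n_bands)
        low = ratio_from_windows(axis, 1.0, [(500, 600, 1.2)])
        with pytest.raises(ValueError):
            StressEffect(ratio_low=low, ratio_high=high)


class TestGenerateScene:
    def test_noiseless_control_equals_endmember(self, noiseless_scene, noiseless_models):
        cube, mask, _ = noiseless_scene
        assert np.allclose(cube.data[mask], noiseless_models.spectral.endmember)

    def test_stress_ratio_recovered_exactly(self, noiseless_models, panel_region):
        kwargs = dict(day_index=3, session="noon")
        control = generate_scene(
            noiseless_models, make_meta(panel_region, **kwargs), SCENE_SHAPE, return_mask=True
        )
        high = generate_scene(
            noiseless_models,
            make_meta(panel_region, treatment="high", **kwargs),
            SCENE_SHAPE,
            return_mask=True,
        )
        ratio = high[0].data[high[1]].mean(axis=0) / control[0].data[control[1]].mean(axis=0)
        assert np.allclose(ratio, noiseless_models.stress.ratio_high, rtol=1e-9)

    def test_growth_follows_schedule(self, noiseless_models, panel_region):
        day0 = generate_scene(
            noiseless_models, make_meta(panel_region), SCENE_SHAPE, return_mask=True
        )[1]
        day6 = generate_scene(
            noiseless_models, make_meta(panel_region, day_index=6), SCENE_SHAPE, return_mask=True
        )[1]
        # soybean grows ~4-fold over the study, up to rasterization
        assert day6.sum() / day0.sum() == pytest.approx(4.0, rel=0.1)

    def test_growth_monotone_across_days(self, noiseless_models, panel_region):
        areas = [
            generate_scene(
                noiseless_models, make_meta(panel_region, day_index=d), SCENE_SHAPE, return_mask=True
            )[1].sum()
            for d in range(7)
        ]
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_scene_too_small_rejected(self, noiseless_models, panel_region):
        with pytest.raises(ValueError):
            generate_scene(noiseless_models, make_meta(panel_region, day_index=6), (20, 20))

    def test_seed_determinism(self, panel_region):
        models = default_models("soybean", scene_shape=SCENE_SHAPE)
        meta = make_meta(panel_region, seed=77)
        a = generate_scene(models, meta, SCENE_SHAPE)
        b = generate_scene(models, meta, SCENE_SHAPE)
        assert np.array_equal(a.data, b.data)

    def test_growth_model_validation(self):
        with pytest.raises(ValueError):
            GrowthModel(area_day0=0, fold_total=4)
        with pytest.raises(ValueError):
            GrowthModel(area_day0=10, fold_total=4, schedule=(0, 5, 3))


class TestGenerateStudy:
    def test_full_plan_yields_336_per_species(self):
        plan = ScenePlan(species=("soybean",))
        assert plan.n_combinations_per_species == 336

    def test_reduced_plan_product(self):
        plan = ScenePlan(species=("soybean",), n_days=2, replicates=2)
        scenes = list(
            generate_study(plan, scene_shape=(60, 60), noise=NoiseModel.none())
        )
        assert len(scenes) == 2 * 2 * 3 * 2

    def test_day0_scenes_are_baseline(self):
        plan = ScenePlan(species=("soybean",), n_days=2, replicates=1)
        for _, meta in generate_study(plan, scene_shape=(60, 60), noise=NoiseModel.none()):
            if meta.day_index == 0:
                assert meta.treatment == "baseline"
            else:
                assert meta.treatment in ("control", "low", "high")

    def test_same_seed_bit_identical(self):
        plan = ScenePlan(species=("coleus",), n_days=1, replicates=2, seed=5)
        first = [c.data for c, _ in generate_study(plan, scene_shape=(60, 60))]
        second = [c.data for c, _ in generate_study(plan, scene_shape=(60, 60))]
        assert all(np.array_equal(a, b) for a, b in zip(first, second))

    def test_plant_factor_constant_within_plant(self):
        # the biological factor must not jump between a plant's acquisitions:
        # in a noiseless-except-replicate study, noon control spectra of the
        # same plant on the same day coincide across sessions only if the
        # factor is shared; check via two days of one plant
        plan = ScenePlan(
            species=("soybean",), n_days=2, replicates=1, seed=3, treatments=("control",)
        )
        noise = NoiseModel(
            pixel_scale_sd=0, replicate_sd=0.1, acquisition_jitter_sd=0, panel_sd=0
        )
        models = default_models("soybean", scene_shape=(60, 60), noise=noise)
        models.spectral.pixel_sd[:] = 0
        scenes = {
            (m.day_index, m.session, m.treatment): c
            for c, m in generate_study(plan, models={"soybean": models}, scene_shape=(60, 60))
        }
        em = models.spectral.endmember
        f_noon = scenes[(1, "noon", "control")].data[30, 30] / (
            em * models.aging.ratio_at(7)
        )
        f_day0 = scenes[(0, "noon", "baseline")].data[30, 30] / em
        assert np.allclose(f_noon, f_day0, rtol=1e-9)
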