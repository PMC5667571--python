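"""Fixture generators: determinism, internal consistency, truth retention."""

import dataclasses

import numpy as np
import pytest

from vpmgpp.indices import compute_vi_series, decode_qa
from vpmgpp.lue import C4FractionMaps, crop_c4_ratio, epsilon0_map
from vpmgpp.synthetic import (
    generate_climate,
    generate_landcover_c4,
    generate_reflectance_cube,
    noise_free,
    true_gpp_oracle,
)


class TestReflectanceFixture:
    def test_no_gaps_all_clear_and_noise_only(self, small_spec):
        spec = dataclasses.replace(small_spec, gap_probability=0.0)
        fix = generate_reflectance_cube(spec)
        flags = decode_qa(fix.cube.qa_word)
        assert flags.evi_usable.all()
        vi = compute_vi_series(fix.cube)
        # observed EVI recovered from inverted bands = truth + noise
        resid = vi.evi - fix.truth_evi
        assert np.abs(resid).max() < 5 * spec.noise_sigma + 1e-6
        assert resid.std() == pytest.approx(spec.noise_sigma, rel=0.2)

    def test_band_inversion_is_exact_without_noise(self, small_spec):
        fix = generate_reflectance_cube(noise_free(small_spec))
        vi = compute_vi_series(fix.cube)
        np.testing.assert_allclose(vi.evi, fix.truth_evi, atol=1e-12)
        np.testing.assert_allclose(vi.lswi, fix.truth_lswi, atol=1e-12)

    def test_gap_probability_one_flags_everything(self, small_spec):
        spec = dataclasses.replace(small_spec, gap_probability=1.0)
        fix = generate_reflectance_cube(spec)
        assert not decode_qa(fix.cube.qa_word).evi_usable.any()

    def test_flagged_fraction_near_target(self, default_spec):
        fix = generate_reflectance_cube(default_spec)
        frac = fix.cloudy.mean()
        assert frac == pytest.approx(default_spec.gap_probability, abs=0.05)

    def test_seeded_determinism(self, small_spec):
        a = generate_reflectance_cube(small_spec)
        b = generate_reflectance_cube(small_spec)
        np.testing.assert_array_equal(a.cube.nir, b.cube.nir)
        np.testing.assert_array_equal(a.cube.qa_word, b.cube.qa_word)
        c = generate_reflectance_cube(dataclasses.replace(small_spec, seed=99))
        assert not np.array_equal(a.cube.nir, c.cube.nir)


class TestClimateFixture:
    def test_tmax_at_least_tmean(self, small_spec):
        fix = generate_climate(small_spec)
        for year in small_spec.years:
            assert (fix.tmax[year] >= fix.tmean[year]).all()
            assert (fix.dswrf[year] >= 0).all()

    def test_zero_amplitude_constant_fields(self, small_spec):
        spec = dataclasses.replace(
            noise_free(small_spec), t_seasonal_amplitude=0.0,
            sw_seasonal_amplitude=0.0,
        )
        fix = generate_climate(spec)
        year = spec.years[0]
        assert np.ptp(fix.dswrf[year]) == pytest.approx(0.0)
        # temperature varies only with the static latitude gradient
        assert np.ptp(fix.tmean[year], axis=0).max() == pytest.approx(0.0)

    def test_seeded_determinism(self, small_spec):
        a = generate_climate(small_spec)
        b = generate_climate(small_spec)
        year = small_spec.years[0]
        np.testing.assert_array_equal(a.tmean[year], b.tmean[year])


class TestLandcoverFixture:
    def test_truth_eps0_matches_pipeline_lookup_exactly(self, small_spec, params):
        land = generate_landcover_c4(small_spec)
        maps = C4FractionMaps(
            crop_ratio=crop_c4_ratio(land.crop_c4_pct, land.total_crop_pct),
            crop_grid=land.crop_grid,
            natural_ratio=land.natural_ratio,
            natural_grid=land.natural_grid,
        )
        eps0 = epsilon0_map(land.igbp, small_spec.grid, maps, params)
        np.testing.assert_allclose(eps0, land.truth_eps0, atol=1e-12)

    def test_all_c3_patches_give_base_eps0(self, small_spec, params):
        from vpmgpp.synthetic import PatchSpec
        spec = dataclasses.replace(
            small_spec,
            patches=(PatchSpec("ENF", 0.25, 0.35, 200.0),) * 4,
        )
        land = generate_landcover_c4(spec)
        np.testing.assert_allclose(land.truth_eps0, 0.42)

    def test_pure_c4_grassland(self, small_spec):
        from vpmgpp.synthetic import PatchSpec
        spec = dataclasses.replace(
            small_spec,
            patches=(PatchSpec("GRA", 0.15, 0.45, 190.0),) * 4,
            natural_c4_ratio_range=(1.0, 1.0),
        )
        land = generate_landcover_c4(spec)
        np.testing.assert_allclose(land.truth_eps0, 0.63, atol=1e-12)


class TestOracle:
    def test_linearity_in_par(self, rng):
        evi = rng.uniform(0.2, 0.8, 20)
        args = dict(
            lswi=rng.uniform(-0.2, 0.4, 20), lswi_max=0.5,
            t_day=rng.uniform(5, 30, 20), eps0=0.42,
            t_min=-1.0, t_max=40.0, t_opt=20.0,
        )
        par = rng.uniform(10, 40, 20)
        g1 = true_gpp_oracle(evi, par=par, **args)
        g2 = true_gpp_oracle(evi, par=2 * par, **args)
        np.testing.assert_allclose(g2, 2 * g1)

    def test_zero_below_fpar_cutoff(self):
        out = true_gpp_oracle(
            np.array([0.05, 0.1]), lswi=0.2, lswi_max=0.5, t_day=20.0,
            par=30.0, eps0=0.42, t_min=-1.0, t_max=40.0, t_opt=20.0,
        )
        np.testing.assert_array_equal(out, 0.0)
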