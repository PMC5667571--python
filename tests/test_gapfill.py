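"""Reference-curve construction, BISE spike rejection and anomaly filling."""

import dataclasses

import numpy as np
import pytest

from vpmgpp.compositing import N_COMPOSITES
from vpmgpp.gapfill import (
    bise_filter,
    build_reference,
    fill_anomalies,
    interpolate_and_smooth,
    interpolate_gaps,
    reconstruct_evi,
)
from vpmgpp.indices import VISeries, compute_vi_series, decode_qa, mask_bad_observations
from vpmgpp.synthetic import generate_reflectance_cube


def _masked_series(spec):
    fix = generate_reflectance_cube(spec)
    vi = compute_vi_series(fix.cube)
    return fix, mask_bad_observations(vi, decode_qa(fix.cube.qa_word))


class TestBise:
    def test_monotone_series_untouched(self):
        values = np.linspace(0.1, 0.8, 10)
        valid = np.ones(10, bool)
        np.testing.assert_array_equal(bise_filter(values, valid), valid)

    def test_cloud_dip_rejected(self):
        values = np.array([0.5, 0.5, 0.1, 0.5, 0.5])
        keep = bise_filter(values, np.ones(5, bool))
        np.testing.assert_array_equal(keep, [True, True, False, True, True])

    def test_genuine_senescence_retained(self):
        values = np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        keep = bise_filter(values, np.ones(5, bool))
        assert keep.all()

    def test_consecutive_contamination_cascades(self):
        values = np.array([0.5, 0.1, 0.12, 0.5, 0.5])
        keep = bise_filter(values, np.ones(5, bool))
        np.testing.assert_array_equal(keep, [True, False, False, True, True])

    def test_all_invalid_returns_all_invalid(self):
        valid = np.zeros(5, bool)
        assert not bise_filter(np.zeros(5), valid).any()

    def test_recovery_outside_window_not_a_spike(self):
        # dip recovers only 7 composites later: outside the 5-composite window
        values = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.5])
        valid = np.ones(9, bool)
        keep = bise_filter(values, valid, window=5)
        assert keep[1]


class TestInterpolateAndSmooth:
    def test_quadratic_is_reproduced_exactly(self):
        x = np.arange(20, dtype=float)
        series = 0.01 * x**2 - 0.1 * x + 0.3
        out = interpolate_and_smooth(series, np.ones(20, bool))
        np.testing.assert_allclose(out, series, atol=1e-12)

    def test_linear_gap_midpoint(self):
        series = np.full(8, np.nan)
        valid = np.zeros(8, bool)
        series[1], series[5] = 0.2, 0.6
        valid[1] = valid[5] = True
        filled = interpolate_gaps(series, valid)
        assert filled[3] == pytest.approx(0.4)
        # ends extended with nearest valid value
        assert filled[0] == pytest.approx(0.2)
        assert filled[7] == pytest.approx(0.6)

    def test_smoothing_reduces_noise(self, rng):
        x = np.arange(N_COMPOSITES)
        truth = 0.4 + 0.3 * np.sin(2 * np.pi * x / N_COMPOSITES)
        noisy = truth + rng.normal(0, 0.02, truth.shape)
        smoothed = interpolate_and_smooth(noisy, np.ones(truth.shape, bool))
        assert np.sqrt(np.mean((smoothed - truth) ** 2)) < np.sqrt(
            np.mean((noisy - truth) ** 2)
        )

    def test_too_few_points_unfillable(self):
        series = np.zeros(10)
        valid = np.zeros(10, bool)
        valid[3] = True
        with pytest.raises(ValueError, match="valid points"):
            interpolate_and_smooth(series, valid)


class TestBuildReference:
    def test_constant_years_give_constant_reference(self):
        evi = np.full((3, N_COMPOSITES, 2, 2), 0.3)
        valid = np.ones(evi.shape, bool)
        ref = build_reference(evi, valid)
        np.testing.assert_allclose(ref.values, 0.3, atol=1e-12)
        assert ref.fillable.all()

    def test_even_count_median_is_mean_of_central_pair(self):
        evi = np.zeros((2, N_COMPOSITES, 1))
        evi[0, 10, 0], evi[1, 10, 0] = 0.3, 0.5
        valid = np.zeros(evi.shape, bool)
        valid[:, 10, 0] = True
        # give enough coverage elsewhere to stay fillable
        valid[0, ::2, 0] = True
        ref = build_reference(evi, valid)
        assert ref.median[10, 0] == pytest.approx(0.4)

    def test_sinusoid_recovered_through_gaps(self, rng):
        n_years = 5
        x = np.arange(N_COMPOSITES)
        truth = 0.4 + 0.25 * np.cos(2 * np.pi * (x - 25) / N_COMPOSITES)
        evi = np.tile(truth, (n_years, 1))[:, :, None]
        valid = rng.random((n_years, N_COMPOSITES, 1)) > 0.3
        ref = build_reference(evi, valid)
        assert ref.fillable.all()
        assert np.max(np.abs(ref.values[:, 0] - truth)) < 0.05

    def test_insufficient_coverage_marks_unfillable(self):
        evi = np.full((2, N_COMPOSITES, 1), 0.4)
        valid = np.zeros(evi.shape, bool)
        valid[:, :10, :] = True  # only 10 of 46 composite indices covered
        ref = build_reference(evi, valid)
        assert not ref.fillable.any()
        assert np.isnan(ref.values).all()

    def test_reference_invariant_to_year_order(self, rng):
        evi = rng.uniform(0.1, 0.8, (4, N_COMPOSITES, 3))
        valid = rng.random(evi.shape) > 0.25
        ref1 = build_reference(evi, valid)
        perm = [2, 0, 3, 1]
        ref2 = build_reference(evi[perm], valid[perm])
        np.testing.assert_array_equal(ref1.values, ref2.values)


class TestFillAnomalies:
    def _reference(self):
        x = np.arange(N_COMPOSITES)
        return 0.3 + 0.2 * np.cos(2 * np.pi * (x - 25) / N_COMPOSITES)

    def test_zero_anomaly_year_reproduces_reference(self, rng):
        ref = self._reference()
        valid = rng.random(N_COMPOSITES) > 0.4
        filled, flags = fill_anomalies(np.where(valid, ref, np.nan), valid, ref)
        np.testing.assert_allclose(filled, ref, atol=1e-10)
        np.testing.assert_array_equal(flags, ~valid)

    def test_constant_offset_preserved_through_gaps(self, rng):
        ref = self._reference()
        year = ref + 0.1
        valid = np.ones(N_COMPOSITES, bool)
        valid[rng.permutation(N_COMPOSITES)[:23]] = False
        filled, _ = fill_anomalies(np.where(valid, year, np.nan), valid, ref)
        np.testing.assert_allclose(filled, year, atol=1e-9)

    def test_whole_year_invalid_returns_reference(self):
        ref = self._reference()
        filled, flags = fill_anomalies(
            np.full(N_COMPOSITES, np.nan), np.zeros(N_COMPOSITES, bool), ref
        )
        np.testing.assert_array_equal(filled, ref)
        assert flags.all()

    def test_long_spring_gap_follows_reference_shape(self):
        # first 6 composites missing while the reference greens up:
        # the fill must track the reference's rise, not extrapolate flat
        ref = self._reference()
        valid = np.ones(N_COMPOSITES, bool)
        valid[:6] = False
        filled, _ = fill_anomalies(np.where(valid, ref, np.nan), valid, ref)
        spring_shape = np.diff(ref[:6])
        filled_shape = np.diff(filled[:6])
        np.testing.assert_allclose(filled_shape, spring_shape, atol=1e-9)


class TestReconstruct:
    def test_gap_positions_recovered(self, default_spec):
        fix, masked = _masked_series(default_spec)
        filled, flags, ref = reconstruct_evi(masked)
        gaps = ~masked.evi_valid & np.isfinite(filled.evi)
        rmse = np.sqrt(np.mean((filled.evi[gaps] - fix.truth_evi[gaps]) ** 2))
        assert rmse < 0.03

    def test_flag_bookkeeping(self, small_spec):
        _, masked = _masked_series(small_spec)
        filled, flags, ref = reconstruct_evi(masked)
        fillable = np.broadcast_to(ref.fillable, flags.shape)
        # flags on fillable pixels cover at least every masked observation
        assert (flags[fillable] | masked.evi_valid[fillable]).all()
        # valid raw observations that survived BISE are not flagged
        raw_kept = masked.evi_valid & ~flags
        assert np.isfinite(filled.evi[raw_kept & fillable]).all()

    def test_determinism(self, small_spec):
        _, masked1 = _masked_series(small_spec)
        _, masked2 = _masked_series(small_spec)
        out1 = reconstruct_evi(masked1)
        out2 = reconstruct_evi(masked2)
        np.testing.assert_array_equal(out1[0].evi, out2[0].evi)
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_valid_output_close_to_raw_on_clean_fixture(self, small_spec):
        spec = dataclasses.replace(small_spec, gap_probability=0.0)
        fix, masked = _masked_series(spec)
        filled, flags, _ = reconstruct_evi(masked)
        # untouched observations deviate from raw only through the SG response
        delta = np.abs(filled.evi - masked.evi)[masked.evi_valid & ~flags]
        assert np.percentile(delta, 99) < 3 * spec.noise_sigma

    def test_flags_monotone_with_masking(self, small_spec):
        _, masked = _masked_series(small_spec)
        _, flags1, _ = reconstruct_evi(masked)
        more = masked.copy()
        more.evi_valid[:, 5, :] = False
        more.evi = np.where(more.evi_valid, more.evi, np.nan)
        _, flags2, _ = reconstruct_evi(more)
        assert (flags2 | ~flags1).all()  # flags1 => flags2
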