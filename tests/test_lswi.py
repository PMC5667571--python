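"""LSWI year substitution and the second-largest LSWI_max rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpmgpp.compositing import N_COMPOSITES
from vpmgpp.indices import VISeries
from vpmgpp.lswi import (
    annual_lswi_max,
    second_largest,
    smooth_lswi_max,
    substitute_missing_years,
)


def _series(years, lswi_by_year, valid_by_year):
    calendar = [(y, k) for y in years for k in range(1, N_COMPOSITES + 1)]
    lswi = np.concatenate([lswi_by_year[y] for y in years])
    valid = np.concatenate([valid_by_year[y] for y in years])
    shape = lswi.shape
    return VISeries(
        evi=np.zeros(shape), lswi=lswi,
        evi_valid=np.ones(shape, bool), lswi_valid=valid,
        calendar=calendar,
    )


class TestYearSubstitution:
    def _two_years(self, target_valid):
        years = (2000, 2001)
        l2000 = np.full((N_COMPOSITES, 1, 1), 0.1)
        l2001 = np.full((N_COMPOSITES, 1, 1), 0.7)
        valid = {
            2000: target_valid,
            2001: np.ones((N_COMPOSITES, 1, 1), bool),
        }
        return _series(years, {2000: l2000, 2001: l2001}, valid)

    def test_entirely_missing_year_equals_source(self):
        vi = self._two_years(np.zeros((N_COMPOSITES, 1, 1), bool))
        out = substitute_missing_years(vi, {2000: 2001})
        np.testing.assert_array_equal(out.lswi[:N_COMPOSITES], 0.7)
        assert out.lswi_valid[:N_COMPOSITES].all()

    def test_complete_year_unchanged(self):
        vi = self._two_years(np.ones((N_COMPOSITES, 1, 1), bool))
        out = substitute_missing_years(vi, {2000: 2001})
        np.testing.assert_array_equal(out.lswi[:N_COMPOSITES], 0.1)

    def test_only_missing_composites_replaced(self):
        valid = np.ones((N_COMPOSITES, 1, 1), bool)
        valid[[0, 1]] = False
        vi = self._two_years(valid)
        out = substitute_missing_years(vi, {2000: 2001})
        np.testing.assert_array_equal(out.lswi[:2].ravel(), [0.7, 0.7])
        np.testing.assert_array_equal(out.lswi[2:N_COMPOSITES], 0.1)

    def test_missing_source_year_raises(self):
        vi = self._two_years(np.zeros((N_COMPOSITES, 1, 1), bool))
        with pytest.raises(ValueError, match="source year"):
            substitute_missing_years(vi, {2000: 2015})


class TestAnnualMax:
    def test_plain_maximum(self):
        lswi = np.linspace(-0.2, 0.55, N_COMPOSITES)[:, None]
        ones = np.ones((N_COMPOSITES, 1), bool)
        assert annual_lswi_max(lswi, ones, ones)[0] == pytest.approx(0.55)

    def test_snow_peak_excluded(self):
        lswi = np.full((N_COMPOSITES, 1), 0.1)
        lswi[5] = 0.9
        lswi[20] = 0.5
        snowfree = np.ones((N_COMPOSITES, 1), bool)
        snowfree[5] = False
        out = annual_lswi_max(lswi, np.ones_like(snowfree), snowfree)
        assert out[0] == pytest.approx(0.5)

    def test_single_snowfree_composite(self):
        lswi = np.full((N_COMPOSITES, 1), 0.9)
        snowfree = np.zeros((N_COMPOSITES, 1), bool)
        snowfree[30] = True
        lswi[30] = 0.2
        assert annual_lswi_max(lswi, np.ones_like(snowfree), snowfree)[0] == \
            pytest.approx(0.2)

    def test_no_snowfree_composites_invalid(self):
        lswi = np.full((N_COMPOSITES, 1), 0.4)
        none = np.zeros((N_COMPOSITES, 1), bool)
        assert np.isnan(annual_lswi_max(lswi, np.ones_like(none), none)[0])


class TestSecondLargestSmoothing:
    def test_five_year_window_worked_example(self):
        raw = np.array([0.5, 0.7, 0.6, 0.8, 0.65])[:, None]
        out = smooth_lswi_max(raw)
        assert out[2, 0] == pytest.approx(0.7)

    def test_constant_series(self):
        raw = np.full((6, 1), 0.4)
        np.testing.assert_allclose(smooth_lswi_max(raw), 0.4)

    def test_truncated_start_window(self):
        raw = np.array([0.9, 0.3, 0.5, 0.1, 0.1, 0.1])[:, None]
        out = smooth_lswi_max(raw)
        assert out[0, 0] == pytest.approx(0.5)  # window {0.9, 0.3, 0.5}

    def test_single_year_returns_itself(self):
        raw = np.array([[0.33]])
        assert smooth_lswi_max(raw)[0, 0] == pytest.approx(0.33)

    def test_upward_spike_does_not_propagate(self):
        raw = np.array([0.4, 0.42, 0.95, 0.41, 0.43])[:, None]
        out = smooth_lswi_max(raw)
        # at the spike year the result is the largest non-spike value
        assert out[2, 0] == pytest.approx(0.43)
        assert (out[:, 0] <= 0.43 + 1e-12).all()

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_sort_based_oracle(self, values):
        raw = np.array(values)[:, None]
        out = smooth_lswi_max(raw)
        for y in range(len(values)):
            window = sorted(values[max(0, y - 2): y + 3], reverse=True)
            expected = window[1] if len(window) >= 2 else window[0]
            assert out[y, 0] == pytest.approx(expected)

    def test_never_exceeds_window_maximum(self, rng):
        raw = rng.uniform(-1, 1, (10, 4))
        out = smooth_lswi_max(raw)
        for y in range(10):
            window_max = raw[max(0, y - 2): y + 3].max(axis=0)
            assert (out[y] <= window_max + 1e-12).all()


def test_second_largest_duplicates_count_separately():
    assert second_largest(np.array([0.5, 0.5, 0.2])) == pytest.approx(0.5)
    assert second_largest(np.array([0.7])) == pytest.approx(0.7)
    assert np.isnan(second_largest(np.array([np.nan])))
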