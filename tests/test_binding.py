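"""Rate law, response maps, and germination-region classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporesense import (
    BindingParams,
    RateMap,
    ValidationError,
    bound_fraction,
    classify_concentration,
    germination_rate,
    germination_region,
    log_grid,
    region_boundary_L,
    response_map,
)

conc = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)
pos = st.floats(min_value=1e-4, max_value=1e2, allow_nan=False)


class TestGerminationRate:
    @pytest.mark.parametrize("D", [0.0, 0.01, 5.0])
    def test_zero_L_gives_zero_rate(self, fitted_params, D):
        assert germination_rate(0.0, D, fitted_params) == 0.0

    def test_half_saturation_at_k_l(self, fitted_params):
        assert germination_rate(fitted_params.k_l, 0.0, fitted_params) == pytest.approx(0.5)

    def test_closed_form_value(self, fitted_params):
        # oracle: direct arithmetic on (L/k_l)/(1 + L/k_l + D/k_d)
        expected = (0.1 / 0.026) / (1 + 0.1 / 0.026 + 0.2 / 0.0052)
        assert germination_rate(0.1, 0.2, fitted_params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.08880994671403197, rel=1e-12)

    @given(L=conc, D=conc, alpha=pos, k_l=pos, k_d=pos)
    @settings(max_examples=200, deadline=None)
    def test_rate_equals_alpha_times_bound_fraction(self, L, D, alpha, k_l, k_d):
        p = BindingParams(alpha=alpha, k_l=k_l, k_d=k_d)
        assert germination_rate(L, D, p) == pytest.approx(
            alpha * bound_fraction(L, D, p), rel=1e-12, abs=1e-300
        )

    @given(L=st.floats(1e-3, 1e2), D=st.floats(1e-3, 1e2), scale=st.floats(1.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_concentration(self, fitted_params, L, D, scale):
        base = germination_rate(L, D, fitted_params)
        assert germination_rate(L * scale, D, fitted_params) > base
        assert germination_rate(L, D * scale, fitted_params) < base

    def test_rate_saturates_at_alpha(self, fitted_params):
        assert germination_rate(1e9, 1.0, fitted_params) == pytest.approx(1.0, rel=1e-3)
        assert germination_rate(1e9, 1.0, fitted_params) < fitted_params.alpha

    def test_ratiometric_regime(self, fitted_params):
        """For g*D >= 100*k_l a 10x joint rescale moves the rate < 1%."""
        g, k_l = fitted_params.g, fitted_params.k_l
        D = np.geomspace(100 * k_l / g, 1e3, 25)
        for ratio in (0.1, 1.0, 10.0):
            r1 = germination_rate(ratio * D, D, fitted_params)
            r2 = germination_rate(10 * ratio * D, 10 * D, fitted_params)
            assert np.all(np.abs(r2 - r1) / r1 < 0.01)

    def test_ratio_only_limit(self, fitted_params):
        # rate -> alpha*(L/D)/(g + L/D) when k_l is negligible
        L, D = 50.0, 100.0
        expect = (L / D) / (fitted_params.g + L / D)
        assert germination_rate(L, D, fitted_params) == pytest.approx(expect, rel=1e-3)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(alpha=0.0, k_l=1.0, k_d=1.0), "alpha"),
            (dict(alpha=1.0, k_l=-1.0, k_d=1.0), "k_l"),
            (dict(alpha=1.0, k_l=1.0, k_d=0.0), "k_d"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            BindingParams(**kwargs)

    def test_negative_concentration_rejected(self, fitted_params):
        with pytest.raises(ValidationError, match="L"):
            germination_rate(-0.1, 0.0, fitted_params)
        with pytest.raises(ValidationError, match="D"):
            germination_rate(0.1, -0.5, fitted_params)

    def test_g_recomputed_from_constants(self, fitted_params):
        assert fitted_params.g == fitted_params.k_l / fitted_params.k_d


class TestResponseMap:
    def test_single_origin_cell(self, fitted_params):
        rm = response_map([0.0], [0.0], fitted_params)
        assert rm.rate.shape == (1, 1) and rm.rate[0, 0] == 0.0

    def test_two_by_two_limits(self, fitted_params):
        huge_D = 1e6 * fitted_params.k_d
        rm = response_map([0.0, fitted_params.k_l], [0.0, huge_D], fitted_params)
        assert rm.rate[0, 0] == 0.0 and rm.rate[1, 0] == 0.0
        assert rm.rate[0, 1] == pytest.approx(0.5)
        assert rm.rate[1, 1] == pytest.approx(0.0, abs=1e-5)

    def test_matches_elementwise_rate(self, fitted_params):
        L, D = log_grid(1e-3, 10, 6), log_grid(1e-2, 1, 5)
        rm = response_map(L, D, fitted_params)
        for i, d in enumerate(D):
            for j, l in enumerate(L):
                assert rm.rate[i, j] == germination_rate(l, d, fitted_params)

    def test_monotone_along_axes(self, fitted_params):
        rm = response_map(log_grid(1e-3, 10, 8), log_grid(1e-3, 10, 8), fitted_params)
        assert np.all(np.diff(rm.rate, axis=1) >= 0)  # increasing in L
        assert np.all(np.diff(rm.rate, axis=0) <= 0)  # decreasing in D

    def test_empty_grid_rejected(self, fitted_params):
        with pytest.raises(ValidationError):
            response_map([], [0.0], fitted_params)

    def test_csv_round_trip(self, fitted_params, tmp_path):
        rm = response_map(log_grid(1e-2, 1, 4), log_grid(1e-2, 1, 3), fitted_params)
        path = tmp_path / "map.csv"
        rm.to_csv(path)
        back = RateMap.from_csv(path)
        np.testing.assert_allclose(back.rate, rm.rate)
        np.testing.assert_allclose(back.L_grid, rm.L_grid)


class TestGerminationRegion:
    def test_boundary_at_k_l_for_zero_D(self, fitted_params):
        mask = germination_region(
            [fitted_params.k_l * 0.999, fitted_params.k_l, fitted_params.k_l * 1.01],
            [0.0],
            fitted_params,
            threshold=0.5,
        )
        assert list(mask.inside[0]) == [False, True, True]

    def test_point_outside_region(self, fitted_params):
        # rate(0.05, 0.5) = 0.05/(0.026 + 0.05 + 5*0.5) ~ 0.0194 < 0.1
        rate = germination_rate(0.05, 0.5, fitted_params)
        assert rate == pytest.approx(0.05 / (0.026 + 0.05 + 2.5), rel=1e-12)
        assert classify_concentration(0.05, 0.5, fitted_params, threshold=0.1) == "dormant"

    def test_high_D_boundary_follows_constant_ratio(self, fitted_params):
        """Boundary L/D tends to g*t/(1-t) in the high-D regime (unit log-log slope)."""
        t = 0.1
        D = np.geomspace(1e2 * fitted_params.k_l / fitted_params.g, 1e4, 30)
        L_b = region_boundary_L(D, fitted_params, threshold=t * fitted_params.alpha)
        limit = fitted_params.g * t / (1 - t)
        assert L_b[-1] / D[-1] == pytest.approx(limit, rel=1e-3)
        slopes = np.diff(np.log10(L_b)) / np.diff(np.log10(D))
        assert slopes[-1] == pytest.approx(1.0, abs=1e-3)

    def test_mask_matches_rate_threshold(self, fitted_params):
        L, D = log_grid(1e-3, 10, 10), log_grid(1e-3, 10, 10)
        mask = germination_region(L, D, fitted_params, threshold=0.1)
        rm = response_map(L, D, fitted_params)
        np.testing.assert_array_equal(mask.inside, rm.rate >= 0.1)

    def test_threshold_at_or_above_alpha_rejected(self, fitted_params):
        with pytest.raises(ValidationError):
            germination_region([0.1], [0.0], fitted_params, threshold=1.0)

    def test_trivial_classifications(self, fitted_params):
        assert classify_concentration(0.0, 0.0, fitted_params, threshold=0.1) == "dormant"
        # rate(0.1, 0) = 0.1/0.126 ~ 0.794 > 0.5
        assert classify_concentration(0.1, 0.0, fitted_params, threshold=0.5) == "germinate"
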