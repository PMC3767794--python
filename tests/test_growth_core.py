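"""Growth-quantifier machinery: calibration map, erf, component quantifiers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from growthquant import (
    GrowthParams,
    YieldFactor,
    biomass_predict,
    dimensionless_time,
    erf_value,
    leaf_fraction_model,
    quantifier,
    quantifier_at_time,
)
from conftest import (
    ALABAMA_QUANT_ROWS,
    CALIFORNIA_QUANT_ROWS,
    EXCLUDED_CELLS,
    LIMIT_ROW,
    assert_printed,
    check_quantifier_row,
)

SQRT_PI = math.sqrt(math.pi)


class TestDimensionlessTime:
    @pytest.mark.parametrize(
        "t, expected",
        [(21.2, 0.0), (30.1, 1.1125), (25.9, 0.5875), (35.1, 1.7375)],
    )
    def test_calibrated_affine_map(self, default_params, t, expected):
        assert dimensionless_time(t, default_params) == pytest.approx(
            expected, abs=1e-12
        )

    def test_reference_time_maps_to_zero(self, default_params):
        assert dimensionless_time(default_params.t_ref, default_params) == 0.0

    def test_nan_time_rejected(self, default_params):
        with pytest.raises(ValueError):
            dimensionless_time(math.nan, default_params)

    def test_physical_constructor_reduces_to_affine_map(self):
        # t_ref = mu - tau^2 c / 2 must reproduce the calibrated map exactly
        # when the physical parameters compose to (21.2, 8.0).
        mu, tau, c = 26.0, 8.0, 2 * (26.0 - 21.2) / 64.0
        params = GrowthParams.from_physical(mu=mu, tau=tau, c=c)
        assert params.t_ref == pytest.approx(21.2, abs=1e-12)
        assert dimensionless_time(30.1, params) == pytest.approx(1.1125, abs=1e-12)

    def test_inconsistent_initiation_state_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GrowthParams(t_i=25.0, x_i=0.0)

    @pytest.mark.parametrize("bad", [{"tau": 0.0}, {"tau": -1.0}, {"k": -2.0}])
    def test_invalid_calibration_rejected(self, bad):
        with pytest.raises(ValueError):
            GrowthParams(**bad)


class TestErf:
    @pytest.mark.parametrize(
        "x, printed",
        [(0.650, "0.642"), (1.688, "0.9830"), (0.0, "0"), (math.inf, "1")],
    )
    def test_tabulated_values(self, x, printed):
        assert_printed(erf_value(x), printed)

    @given(st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, x):
        assert erf_value(-x) == pytest.approx(-erf_value(x), abs=1e-15)


class TestQuantifier:
    @pytest.mark.parametrize("row", CALIFORNIA_QUANT_ROWS, ids=lambda r: f"t={r[0]}")
    def test_california_table_reproduced(self, default_params, row):
        t, x_p, erf_p, gauss_p, qs_p, qt_p = row
        p = quantifier_at_time(t, default_params)
        check_quantifier_row(p, x_p, erf_p, gauss_p, qs_p=qs_p, qt_p=qt_p,
                             exclude=EXCLUDED_CELLS.get(("california", t), ()))

    @pytest.mark.parametrize("row", ALABAMA_QUANT_ROWS, ids=lambda r: f"t={r[0]}")
    def test_alabama_table_reproduced(self, default_params, row):
        t, x_p, erf_p, gauss_p, qt_p = row
        p = quantifier_at_time(t, default_params)
        check_quantifier_row(p, x_p, erf_p, gauss_p, qt_p=qt_p,
                             exclude=EXCLUDED_CELLS.get(("alabama", t), ()))

    def test_seasonal_limits(self, default_params):
        p = quantifier_at_time(math.inf, default_params)
        assert p.q_leaf == pytest.approx(1.0, abs=1e-12)
        assert_printed(p.q_struct, LIMIT_ROW["q_struct"])
        assert_printed(p.q_total, LIMIT_ROW["q_total"])
        assert p.q_struct == pytest.approx(9.0 / SQRT_PI, abs=1e-12)

    def test_vanishes_at_initiation(self):
        p = quantifier(0.0, k=9.0, x_i=0.0)
        assert p.q_leaf == p.q_struct == p.q_total == 0.0

    def test_before_initiation_rejected(self):
        with pytest.raises(ValueError, match="initiation"):
            quantifier(-0.1, k=9.0, x_i=0.0)

    @given(
        x=st.floats(0, 5),
        k=st.sampled_from([0.0, 1.0, 9.0]),
    )
    @settings(max_examples=100, deadline=None)
    def test_additivity(self, x, k):
        p = quantifier(x, k=k, x_i=0.0)
        assert p.q_total == p.q_leaf + p.q_struct  # exact identity

    def test_monotone_increasing(self):
        grid = np.linspace(0, 5, 400)
        q = [quantifier(x).q_total for x in grid]
        assert all(b > a for a, b in zip(q, q[1:]))

    @given(st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_k_zero_degenerates_to_erf(self, x):
        p = quantifier(x, k=0.0, x_i=0.0)
        assert p.q_total == pytest.approx(erf_value(x), abs=1e-15)
        assert p.q_struct == 0.0

    def test_nonzero_initiation_state_form(self):
        # General-x_i form: prefactor (1 - k*x_i) on the erf difference and a
        # Gaussian difference on the structural side.
        x, k, x_i = 1.0, 2.0, 0.05
        p = quantifier(x, k=k, x_i=x_i)
        assert p.q_leaf == pytest.approx(
            (1 - k * x_i) * (erf_value(x) - erf_value(x_i)), abs=1e-14
        )
        assert p.q_struct == pytest.approx(
            (k / SQRT_PI) * (math.exp(-x_i**2) - math.exp(-x**2)), abs=1e-14
        )


class TestLeafFraction:
    def test_limit_at_initiation_is_one(self):
        assert leaf_fraction_model(0.0) == 1.0
        assert leaf_fraction_model(1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_late_season_limit(self):
        # Q_L -> 1 and Q_S -> 9/sqrt(pi): f_L -> 1/(1 + 9/sqrt(pi)).
        assert leaf_fraction_model(math.inf) == pytest.approx(
            1.0 / (1.0 + 9.0 / SQRT_PI), abs=1e-12
        )

    def test_mid_season_value_from_components(self):
        # At x = 0.650 the two components are erf(0.65) and the structural
        # term; the printed-table cells 0.642 and 1.75 give ratio ~0.268.
        assert leaf_fraction_model(0.650) == pytest.approx(0.268, abs=0.002)

    def test_strictly_decreasing(self):
        # beyond x ~ 4 both components are saturated to double precision,
        # so strict decrease is asserted on the season's working range
        grid = np.linspace(0.01, 3.5, 300)
        f = [leaf_fraction_model(x) for x in grid]
        assert all(b < a for a, b in zip(f, f[1:]))


class TestBiomassPredict:
    def test_zero_yield_factor(self, default_params):
        assert biomass_predict(30.0, YieldFactor(0.0), default_params) == 0.0

    def test_alabama_end_of_season(self, default_params):
        # A = 1.27 Mg/ha at the last Alabama date, where Q = 5.77.
        y = biomass_predict(34.7, YieldFactor(1.27), default_params)
        assert y == pytest.approx(1.27 * 5.7663, abs=2e-3)

    def test_unit_yield_factor_seasonal_limit(self, default_params):
        assert_printed(
            biomass_predict(math.inf, YieldFactor(1.0), default_params), "6.08"
        )

    def test_before_initiation_rejected(self, default_params):
        with pytest.raises(ValueError, match="initiation"):
            biomass_predict(20.0, YieldFactor(1.0), default_params)

    def test_monotone_in_time(self, default_params):
        times = np.linspace(21.2, 41.2, 100)
        ys = [biomass_predict(t, YieldFactor(1.5), default_params) for t in times]
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_infinite_yield_factor_rejected(self):
        with pytest.raises(ValueError):
            YieldFactor(math.inf)
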