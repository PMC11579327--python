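"""Mass-balance inversion for soil source strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isonox.apportionment import (
    ApportionmentPolicy,
    apportion_series,
    consistent_soil_inversion,
    soil_source_strength,
)
from isonox.core import mix_delta
from isonox.errors import InvalidInputError, SingularityError

DELTA_SOIL = -33.2


class TestSoilSourceStrength:
    def test_imperial_annual_estimate(self):
        # annual-mean δNOx −13.67‰ with the cited a priori −5.04‰
        es = soil_source_strength(-13.67, -5.04, 15.2, DELTA_SOIL)
        assert round(es, 1) == 6.7

    def test_zero_when_observation_matches_apriori(self):
        assert soil_source_strength(-5.04, -5.04, 15.2, DELTA_SOIL) == 0.0

    def test_forward_mixed_toy_case(self):
        es = soil_source_strength(-257.0 / 19.0, -8.28, 15.0, DELTA_SOIL)
        assert es == pytest.approx(4.0, abs=1e-3)

    def test_singularity_guard_band(self):
        with pytest.raises(SingularityError):
            soil_source_strength(-33.0, -5.04, 15.2, DELTA_SOIL)

    def test_nonpositive_inventory_rejected(self):
        with pytest.raises(InvalidInputError):
            soil_source_strength(-13.0, -5.04, 0.0, DELTA_SOIL)

    @given(
        st.floats(min_value=-30.0, max_value=-6.0),
        st.floats(min_value=-30.0, max_value=-6.0),
    )
    def test_strictly_decreasing_in_delta_obs(self, d1, d2):
        """Lighter observed air ⇒ more soil (δ_s below the a priori)."""
        apriori = -5.04
        e1 = soil_source_strength(d1, apriori, 15.2, DELTA_SOIL)
        e2 = soil_source_strength(d2, apriori, 15.2, DELTA_SOIL)
        if d1 < d2:
            assert e1 > e2
        elif d1 > d2:
            assert e1 < e2


class TestConsistentInversion:
    def test_inverts_forward_mixture_exactly(self):
        es = consistent_soil_inversion(
            -257.0 / 19.0, [10.0, 4.0], [-2.5, -16.5], DELTA_SOIL
        )
        assert es == pytest.approx(5.0, abs=1e-9)

    def test_zero_at_nonsoil_mixture_mean(self):
        mean = mix_delta([10.0, 4.0], [-2.5, -16.5])
        es = consistent_soil_inversion(mean, [10.0, 4.0], [-2.5, -16.5], DELTA_SOIL)
        assert es == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_observation_rejected(self):
        # heavier than the non-soil mixture: no non-negative soil flux
        with pytest.raises(InvalidInputError):
            consistent_soil_inversion(-1.0, [10.0, 4.0], [-2.5, -16.5], DELTA_SOIL)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=1, max_size=5),
        st.floats(min_value=0.01, max_value=200.0),
    )
    def test_round_trip_recovers_soil_flux(self, nonsoil_rates, e_true):
        """Forward-mix any positive fluxes, invert, recover to 1e-9."""
        deltas = np.linspace(-2.5, -16.5, len(nonsoil_rates))
        d_obs = mix_delta(
            [*nonsoil_rates, e_true], [*deltas, DELTA_SOIL]
        )
        if abs(d_obs - DELTA_SOIL) < 0.5:
            return  # inside the singular guard band by construction
        es = consistent_soil_inversion(d_obs, nonsoil_rates, deltas, DELTA_SOIL)
        assert es == pytest.approx(e_true, abs=1e-9, rel=1e-9)

    @given(
        st.floats(min_value=0.01, max_value=50.0),
        st.floats(min_value=0.0, max_value=10.0),
    )
    def test_offset_identity(self, e_true, inv_soil):
        """On exact forward-mixed data whose non-soil fluxes match the
        inventory, the inventory-referenced estimator returns
        E_true − α_s·E_inv while the consistent one returns E_true."""
        rates = {"mobile": 10.0, "stationary": 4.0}
        deltas = {"mobile": -2.5, "stationary": -16.5}
        e_inv = sum(rates.values()) + inv_soil
        d_obs = mix_delta(
            [*rates.values(), e_true], [*deltas.values(), DELTA_SOIL]
        )
        if abs(d_obs - DELTA_SOIL) < 0.5:
            return
        apriori = (
            sum(rates[s] * deltas[s] for s in rates) + inv_soil * DELTA_SOIL
        ) / e_inv
        printed = soil_source_strength(d_obs, apriori, e_inv, DELTA_SOIL)
        consistent = consistent_soil_inversion(
            d_obs, list(rates.values()), list(deltas.values()), DELTA_SOIL
        )
        assert printed == pytest.approx(e_true - inv_soil, abs=1e-8, rel=1e-8)
        assert consistent == pytest.approx(e_true, abs=1e-8, rel=1e-8)


def _series(deltas, site="Thermal"):
    return pd.DataFrame({"delta_nox": deltas, "period": range(len(deltas))})


class TestApportionSeries:
    THERMAL_NOX = [-16.1, -8.0, -8.0, -12.0, 0.2, -9.1, -3.2, -12.0, -7.6]

    def test_thermal_monthly_inversion_with_truncation(self):
        per, agg = apportion_series(
            _series(self.THERMAL_NOX), -3.11, 18.0, DELTA_SOIL
        )
        expected = [13.7, 3.5, 3.5, 7.5, 0.0, 4.5, 0.1, 7.5, 3.2]
        assert [round(r.e_soil, 1) for r in per] == expected
        assert agg.e_soil == pytest.approx(4.83, abs=0.01)

    def test_november_truncated_to_zero(self):
        per, _ = apportion_series(_series([0.2]), -3.11, 18.0, DELTA_SOIL)
        (r,) = per
        assert r.truncated and r.e_soil == 0.0
        assert r.e_soil_raw == pytest.approx(-1.78, abs=0.01)

    def test_constant_series_at_apriori_gives_zeros(self):
        per, agg = apportion_series(_series([-3.11] * 4), -3.11, 18.0, DELTA_SOIL)
        assert all(r.e_soil == 0.0 for r in per) and agg.e_soil == 0.0

    def test_missing_samples_dropped_all_missing_rejected(self):
        per, _ = apportion_series(
            _series([np.nan, -8.0, np.nan]), -3.11, 18.0, DELTA_SOIL
        )
        assert len(per) == 1
        with pytest.raises(InvalidInputError):
            apportion_series(_series([np.nan]), -3.11, 18.0, DELTA_SOIL)

    def test_truncated_aggregate_at_least_untruncated(self):
        policy_off = ApportionmentPolicy(truncate_negative=False)
        _, agg_t = apportion_series(_series(self.THERMAL_NOX), -3.11, 18.0, DELTA_SOIL)
        _, agg_u = apportion_series(
            _series(self.THERMAL_NOX), -3.11, 18.0, DELTA_SOIL, policy_off
        )
        assert agg_t.e_soil >= agg_u.e_soil

    def test_aggregate_modes_differ_as_documented(self):
        """Inverting the mean δ is not the mean of inversions (Jensen)."""
        policy = ApportionmentPolicy(aggregate_mode="invert_mean_delta")
        _, agg_inv = apportion_series(
            _series(self.THERMAL_NOX), -3.11, 18.0, DELTA_SOIL, policy
        )
        _, agg_mean = apportion_series(_series(self.THERMAL_NOX), -3.11, 18.0, DELTA_SOIL)
        assert agg_inv.e_soil != pytest.approx(agg_mean.e_soil, abs=0.1)

    def test_sigma_column_filled_and_never_truncated(self):
        per, _ = apportion_series(
            _series([0.2, -8.0]), -3.11, 18.0, DELTA_SOIL, sigma_fn=lambda d: 2.5
        )
        assert all(r.sigma_e_soil == 2.5 for r in per)
        assert per[0].truncated and per[0].sigma_e_soil == 2.5
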