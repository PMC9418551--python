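"""Unit and property tests for the physiological chain.

Frozen expected values were computed once with an independent
high-precision evaluation of the closed forms (see comments) and are
asserted at tight tolerances.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efit.climate_io import Co2Table, MonthlyClimate, SiteRecord
from efit.lue_core import (
    LueParams,
    conversion_efficiency,
    ecosystem_fit,
    evaluate_site,
    gamma_star,
    intercellular_co2,
    net_uptake,
    rubisco_wi,
    tnpp_tmax,
)
from efit.season import GrowingSeason, derive_growing_season

# exp(19.02 - 37.83 / (0.008314 * 298.15)), evaluated independently
GAMMA_25 = 42.89266271111762
# 280 / (4.5*280 + 10.5*GAMMA_25)
WI_280 = 0.16370698485025523
# (1 - GAMMA_25/280) * WI_280
A_280 = 0.13862902597655508
# A_280 * 0.45 * 0.9
EC_280 = 0.05614475552050481
# 16000 * 365 * 0.45 * 0.9 * EC_280 / 1000 / 18.2 * 10
TNPP_UNIFORM = 72.96350316324065


class TestGammaStar:
    def test_closed_form_anchor_at_25C(self, params):
        assert gamma_star(25.0, params) == pytest.approx(GAMMA_25, rel=1e-15)

    def test_within_1pct_of_published_bernacchi_value(self, params):
        # literature sanity anchor ~42.75 umol/mol at 25 degC
        assert abs(gamma_star(25.0, params) - 42.75) / 42.75 < 0.01

    def test_monotone_in_temperature(self, params):
        assert gamma_star(10.0, params) < gamma_star(25.0, params)

    def test_cold_limit_approaches_zero(self, params):
        assert gamma_star(-272.0, params) < 1e-30

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_nonfinite_temperature_rejected(self, bad, params):
        with pytest.raises(ValueError):
            gamma_star(bad, params)

    def test_absolute_zero_rejected(self, params):
        with pytest.raises(ValueError):
            gamma_star(-273.15, params)


class TestIntercellularCo2:
    def test_400_gives_280(self, params):
        assert intercellular_co2(400.0, params) == pytest.approx(280.0)

    def test_nonpositive_ca_rejected(self, params):
        with pytest.raises(ValueError):
            intercellular_co2(0.0, params)

    def test_unit_ratio_is_identity(self):
        p = LueParams(ci_ratio=1.0)
        assert intercellular_co2(413.2, p) == pytest.approx(413.2)


class TestRubiscoWi:
    def test_worked_value(self):
        assert rubisco_wi(280.0, GAMMA_25) == pytest.approx(WI_280, rel=1e-15)

    def test_zero_gamma_limit(self):
        assert rubisco_wi(280.0, 0.0) == pytest.approx(1.0 / 4.5, rel=1e-15)

    @given(
        c_i=st.floats(1.0, 2000.0),
        gstar=st.floats(1e-6, 500.0),
    )
    def test_bounded_below_one_over_4p5(self, c_i, gstar):
        assert 0.0 < rubisco_wi(c_i, gstar) < 1.0 / 4.5


class TestNetUptake:
    def test_worked_value(self):
        assert net_uptake(280.0, GAMMA_25) == pytest.approx(A_280, rel=1e-15)

    def test_zero_at_compensation_point(self):
        assert net_uptake(42.9, 42.9) == pytest.approx(0.0, abs=1e-15)

    def test_increasing_in_ci(self):
        vals = [net_uptake(c, GAMMA_25) for c in (100.0, 200.0, 400.0, 800.0)]
        assert vals == sorted(vals)

    def test_negative_below_compensation_point(self):
        assert net_uptake(20.0, GAMMA_25) < 0.0


class TestConversionEfficiency:
    def test_worked_value(self, params):
        assert conversion_efficiency(A_280, params) == pytest.approx(EC_280, rel=1e-15)

    def test_zero_maps_to_zero(self, params):
        assert conversion_efficiency(0.0, params) == 0.0

    def test_unit_efficiencies_identity(self):
        p = LueParams(beta=1.0, alpha_leaf=1.0)
        assert conversion_efficiency(0.1234, p) == pytest.approx(0.1234)

    @given(
        temp=st.floats(-20.0, 40.0),
        c_a=st.floats(200.0, 900.0),
    )
    @settings(max_examples=200)
    def test_global_bound(self, temp, c_a):
        p = LueParams()
        g = gamma_star(temp, p)
        a = net_uptake(intercellular_co2(c_a, p), g)
        ec = conversion_efficiency(a, p)
        assert ec < p.beta * p.alpha_leaf / 4.5


def _season(days=365, temp=25.0, srad=16000.0):
    return GrowingSeason(
        g_days=days, g_temp=temp, g_srad=srad, months_used=frozenset(range(12))
    )


class TestTnppTmax:
    def test_worked_value(self, params):
        assert tnpp_tmax(_season(), EC_280, params) == pytest.approx(
            TNPP_UNIFORM, rel=1e-15
        )

    def test_empty_season_zero(self, params):
        gs = GrowingSeason(g_days=0, g_temp=math.nan, g_srad=math.nan)
        assert tnpp_tmax(gs, EC_280, params) == 0.0

    def test_linear_in_srad(self, params):
        t1 = tnpp_tmax(_season(srad=8000.0), EC_280, params)
        t2 = tnpp_tmax(_season(srad=16000.0), EC_280, params)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_linear_in_days(self, params):
        t1 = tnpp_tmax(_season(days=100), EC_280, params)
        t2 = tnpp_tmax(_season(days=200), EC_280, params)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_undefined_srad_with_days_raises(self, params):
        gs = GrowingSeason(g_days=200, g_temp=10.0, g_srad=math.nan)
        with pytest.raises(ValueError):
            tnpp_tmax(gs, EC_280, params)

    def test_literal_form_differs_and_matches_its_formula(self, params):
        gs = _season()
        literal = tnpp_tmax(gs, EC_280, params, literal_form=True)
        expected = 16000.0 * EC_280 * 0.9 * 0.9 / 1000.0 / 18.2 * 10.0
        assert literal == pytest.approx(expected, rel=1e-12)
        assert literal != pytest.approx(TNPP_UNIFORM)


class TestEcosystemFit:
    def test_identity_ratio_is_100_percent(self):
        assert ecosystem_fit(72.9635, 72.9635) == pytest.approx(100.0)

    def test_worked_percent(self):
        assert ecosystem_fit(22.0, TNPP_UNIFORM) == pytest.approx(
            30.1520610253315, rel=1e-12
        )

    def test_ratio_scale(self):
        assert ecosystem_fit(22.0, 44.0, percent=False) == pytest.approx(0.5)

    def test_zero_max_raises(self):
        with pytest.raises(ZeroDivisionError):
            ecosystem_fit(10.0, 0.0)

    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_joint_scaling(self, scale):
        base = ecosystem_fit(22.0, 70.0)
        assert ecosystem_fit(22.0 * scale, 70.0 * scale) == pytest.approx(
            base, rel=1e-9
        )


class TestLueParams:
    @pytest.mark.parametrize(
        "field,value",
        [("beta", 1.5), ("beta", 0.0), ("eps_i", -0.1), ("spec_energy_K", 0.0)],
    )
    def test_bounds_enforced(self, field, value):
        with pytest.raises(ValueError):
            LueParams(**{field: value})

    def test_defaults(self, params):
        assert params.spec_energy_K == 18.2
        assert params.ci_ratio == 0.7
        assert params.gas_const_R == 0.008314

    def test_unknown_override_rejected(self, params):
        with pytest.raises(ValueError):
            params.with_overrides(not_a_param=1.0)


class TestEvaluateSite:
    def test_uniform_worked_site(self, uniform_site, uniform_climate, co2_400, params):
        res = evaluate_site(uniform_site, uniform_climate, co2_400, params)
        assert res.g_days == 365
        assert res.c_a == 400.0
        assert res.c_i == pytest.approx(280.0)
        assert res.gamma_star == pytest.approx(GAMMA_25, rel=1e-14)
        assert res.tnpp_tmax == pytest.approx(TNPP_UNIFORM, rel=1e-14)
        assert res.efit == pytest.approx(30.1520610253315, rel=1e-12)
        assert res.flags == []

    def test_all_frozen_site(self, uniform_site, frozen_climate, co2_400, params):
        res = evaluate_site(uniform_site, frozen_climate, co2_400, params)
        assert res.tnpp_tmax == 0.0
        assert math.isnan(res.efit)
        assert "empty_season" in res.flags
        assert "efit_undefined" in res.flags

    def test_determinism(self, uniform_site, uniform_climate, co2_400, params):
        r1 = evaluate_site(uniform_site, uniform_climate, co2_400, params)
        r2 = evaluate_site(uniform_site, uniform_climate, co2_400, params)
        assert r1 == r2

    def test_missing_co2_year_flagged_not_raised(
        self, uniform_site, uniform_climate, params
    ):
        co2 = Co2Table(ppm_by_year={1990: 354.45})
        res = evaluate_site(uniform_site, uniform_climate, co2, params)
        assert any(f.startswith("co2_lookup_failed") for f in res.flags)
        assert math.isnan(res.tnpp_tmax)

    def test_efit_above_100_flagged(self, uniform_climate, co2_400, params):
        site = SiteRecord(site_id="H", lon=0, lat=0, year=2000, tnpp_obs=500.0)
        res = evaluate_site(site, uniform_climate, co2_400, params)
        assert res.efit > 100.0
        assert "efit_above_100" in res.flags

    def test_no_obs_no_efit(self, uniform_climate, co2_400, params):
        site = SiteRecord(site_id="N", lon=0, lat=0, year=2000)
        res = evaluate_site(site, uniform_climate, co2_400, params)
        assert res.tnpp_tmax > 0
        assert math.isnan(res.efit)
        assert "efit_undefined" not in res.flags


def script_transcription(temp, srad, c_a):
    """Independent straight-line transcription of the reference formulas;
    used as the dual-route oracle for evaluate_site."""
    month_days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    warm = [m for m in range(12) if temp[m] >= 0.0]
    if not warm:
        return 0.0, None
    g_t = sum(temp[m] for m in warm) / len(warm)
    g_s = sum(srad[m] for m in warm) / len(warm)
    g_d = sum(month_days[m] for m in warm)
    gamma = math.exp(19.02 - 37.83 / (0.008314 * (g_t + 273.15)))
    ci = c_a * 0.7
    wj = ci / (4.5 * ci + 10.5 * gamma)
    a = (1.0 - gamma / ci) * wj
    ec = a * 0.45 * 0.9
    tmax = g_s * g_d * 0.45 * 0.9 * ec / 1000.0 / 18.2 * 10.0
    return tmax, ec


class TestOracleEquivalence:
    def test_100_random_sites_match_transcription(self, params):
        rng = np.random.default_rng(42)
        co2 = Co2Table(ppm_by_year={2000: 380.0})
        for i in range(100):
            temp = rng.uniform(-15.0, 30.0, 12)
            srad = rng.uniform(2000.0, 25000.0, 12)
            climate = MonthlyClimate(temp=temp, srad=srad)
            site = SiteRecord(site_id=f"R{i}", lon=0.0, lat=0.0, year=2000)
            res = evaluate_site(site, climate, co2, params)
            expected, _ = script_transcription(temp, srad, 380.0)
            if expected == 0.0:
                assert res.tnpp_tmax == 0.0
            else:
                assert res.tnpp_tmax == pytest.approx(expected, rel=1e-10)


class TestMonotonicityProperties:
    def test_randomized_probes(self, params):
        rng = np.random.default_rng(7)
        for _ in range(250):
            t = rng.uniform(-10.0, 35.0)
            dt = rng.uniform(0.1, 5.0)
            ca = rng.uniform(250.0, 800.0)
            dca = rng.uniform(5.0, 100.0)
            # gamma* increasing in T
            assert gamma_star(t + dt, params) > gamma_star(t, params)
            # eps_c decreasing in T at fixed c_a
            ci = intercellular_co2(ca, params)
            ec_lo = conversion_efficiency(net_uptake(ci, gamma_star(t, params)), params)
            ec_hi = conversion_efficiency(
                net_uptake(ci, gamma_star(t + dt, params)), params
            )
            assert ec_hi < ec_lo
            # eps_c increasing in c_a at fixed T
            g = gamma_star(t, params)
            ec_a = conversion_efficiency(
                net_uptake(intercellular_co2(ca, params), g), params
            )
            ec_b = conversion_efficiency(
                net_uptake(intercellular_co2(ca + dca, params), g), params
            )
            assert ec_b > ec_a
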