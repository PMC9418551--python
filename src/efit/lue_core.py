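"""Physiological core of the light-use-efficiency model.

Chains the CO2 compensation point (Arrhenius form), rubisco-limited
uptake, photosynthetic conversion efficiency, theoretical maximum total
NPP, and the Ecosystem Fit ratio of observed to maximum productivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .climate_io import Co2Table, MonthlyClimate, SiteRecord, co2_for_year
from .season import GrowingSeason, derive_growing_season

__all__ = [
    "LueParams",
    "SiteResult",
    "gamma_star",
    "intercellular_co2",
    "rubisco_wi",
    "net_uptake",
    "conversion_efficiency",
    "tnpp_tmax",
    "ecosystem_fit",
    "evaluate_site",
    "evaluate_batch",
]


@dataclass(frozen=True)
class LueParams:
    """Physiological constants of the model.

    Defaults follow the standard C3 parameterization: molar gas constant in
    kJ mol-1 K-1, dry-biomass specific energy 18.2 MJ kg-1, Arrhenius
    scaling constant 19.02 and activation energy 37.83 kJ mol-1 for the
    compensation point, 45% of absorbed quanta reaching photosystem II,
    90% canopy interception, 90% leaf absorptance, PAR taken as 45% of
    total shortwave radiation, and an intercellular-to-atmospheric CO2
    ratio of 0.7.
    """

    gas_const_R: float = 0.008314  # kJ mol-1 K-1
    spec_energy_K: float = 18.2  # MJ kg-1
    arrh_c: float = 19.02
    arrh_dHa: float = 37.83  # kJ mol-1
    beta: float = 0.45
    eps_i: float = 0.90
    alpha_leaf: float = 0.90
    par_frac: float = 0.45
    ci_ratio: float = 0.70

    def __post_init__(self) -> None:
        for name in ("beta", "eps_i", "alpha_leaf", "par_frac", "ci_ratio"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.spec_energy_K <= 0:
            raise ValueError("spec_energy_K must be positive")
        if self.arrh_dHa <= 0:
            raise ValueError("arrh_dHa must be positive")
        if self.gas_const_R <= 0:
            raise ValueError("gas_const_R must be positive")

    def with_overrides(self, **overrides: float) -> "LueParams":
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass
class SiteResult:
    """All intermediates of the per-site chain, plus status flags."""

    site_id: str
    g_days: int = 0
    g_temp: float = math.nan
    g_srad: float = math.nan
    c_a: float = math.nan
    c_i: float = math.nan
    gamma_star: float = math.nan
    w_i: float = math.nan
    a_net: float = math.nan
    eps_c: float = math.nan
    tnpp_tmax: float = math.nan
    tnpp_obs: float | None = None
    efit: float = math.nan
    flags: list[str] = field(default_factory=list)


def gamma_star(temp_c: float, params: LueParams = LueParams()) -> float:
    """CO2 compensation point without dark respiration (umol mol-1).

    Arrhenius response: exp(c - dHa / (R * T_kelvin)).
    """
    if not math.isfinite(temp_c):
        raise ValueError(f"temperature must be finite, got {temp_c}")
    if temp_c <= -273.15:
        raise ValueError(f"temperature {temp_c} degC at or below absolute zero")
    return math.exp(
        params.arrh_c - params.arrh_dHa / (params.gas_const_R * (temp_c + 273.15))
    )


def intercellular_co2(c_a: float, params: LueParams = LueParams()) -> float:
    """Intercellular CO2 as a fixed fraction of atmospheric CO2."""
    if c_a <= 0:
        raise ValueError(f"c_a must be positive, got {c_a}")
    return c_a * params.ci_ratio


def rubisco_wi(c_i: float, gstar: float) -> float:
    """Rubisco-limited carboxylation term: c_i / (4.5 c_i + 10.5 Gamma*)."""
    if c_i <= 0:
        raise ValueError(f"c_i must be positive, got {c_i}")
    if gstar < 0:
        raise ValueError(f"gamma_star must be non-negative, got {gstar}")
    return c_i / (4.5 * c_i + 10.5 * gstar)


def net_uptake(c_i: float, gstar: float) -> float:
    """Net CO2 uptake efficiency: (1 - Gamma*/c_i) * W_i.

    May be <= 0 when c_i <= Gamma* (below the compensation point); the
    value is returned as-is and callers flag it.
    """
    return (1.0 - gstar / c_i) * rubisco_wi(c_i, gstar)


def conversion_efficiency(a_net: float, params: LueParams = LueParams()) -> float:
    """Photosynthetic conversion efficiency: A * beta * alpha."""
    return a_net * params.beta * params.alpha_leaf


def tnpp_tmax(
    gs: GrowingSeason,
    eps_c: float,
    params: LueParams = LueParams(),
    literal_form: bool = False,
) -> float:
    """Theoretical maximum total NPP in Mg ha-1 yr-1.

    Canonical form: seasonal energy G_srad * G_d * par_frac * eps_i *
    eps_c, converted kJ -> MJ (/1000), divided by the specific energy of
    dry biomass (MJ kg-1 -> kg m-2), then kg m-2 -> Mg ha-1 (*10).
    ``literal_form=True`` drops the day count and PAR fraction and applies
    eps_i a second time (for comparison only; not the default).
    """
    if gs.empty:
        return 0.0
    if not math.isfinite(gs.g_srad):
        raise ValueError("g_srad undefined while g_days > 0")
    if literal_form:
        energy_mj = gs.g_srad * eps_c * params.eps_i * params.eps_i / 1000.0
    else:
        energy_mj = (
            gs.g_srad * gs.g_days * params.par_frac * params.eps_i * eps_c / 1000.0
        )
    return energy_mj / params.spec_energy_K * 10.0


def ecosystem_fit(tnpp_obs: float, tnpp_max: float, percent: bool = True) -> float:
    """Ecosystem Fit: observed over maximum productivity, percent by default."""
    if tnpp_max == 0:
        raise ZeroDivisionError("tnpp_tmax is zero; eFit undefined")
    ratio = tnpp_obs / tnpp_max
    return ratio * 100.0 if percent else ratio


def evaluate_site(
    site: SiteRecord,
    climate: MonthlyClimate,
    co2: Co2Table,
    params: LueParams = LueParams(),
    warm_threshold: float = 0.0,
    strict_threshold: bool = False,
    fallback_ppm: float | None = None,
) -> SiteResult:
    """Run the full chain for one site, recording every intermediate.

    Component failures are captured as flags on the result rather than
    raised, so batch runs never abort on one bad site.
    """
    result = SiteResult(site_id=site.site_id, tnpp_obs=site.tnpp_obs)
    gs = derive_growing_season(climate, warm_threshold, strict_threshold)
    result.g_days = gs.g_days
    result.g_temp = gs.g_temp
    result.g_srad = gs.g_srad
    if not gs.complete:
        result.flags.append("incomplete_climate")

    if gs.empty:
        result.tnpp_tmax = 0.0
        result.flags.append("empty_season")
        if site.tnpp_obs is not None:
            result.flags.append("efit_undefined")
        return result

    try:
        year = site.year if site.year is not None else -1
        result.c_a = co2_for_year(year, co2, fallback_ppm)
    except KeyError as exc:
        result.flags.append(f"co2_lookup_failed: {exc.args[0]}")
        return result

    result.gamma_star = gamma_star(gs.g_temp, params)
    result.c_i = intercellular_co2(result.c_a, params)
    result.w_i = rubisco_wi(result.c_i, result.gamma_star)
    result.a_net = net_uptake(result.c_i, result.gamma_star)
    result.eps_c = conversion_efficiency(result.a_net, params)

    if result.a_net <= 0:
        # below the compensation point: clamp rather than emit negative biomass
        result.tnpp_tmax = 0.0
        result.flags.append("below_compensation_point")
        if site.tnpp_obs is not None:
            result.flags.append("efit_undefined")
        return result

    result.tnpp_tmax = tnpp_tmax(gs, result.eps_c, params)
    if site.tnpp_obs is not None:
        if result.tnpp_tmax == 0:
            result.flags.append("efit_undefined")
        else:
            result.efit = ecosystem_fit(site.tnpp_obs, result.tnpp_tmax)
            if result.efit > 100.0:
                result.flags.append("efit_above_100")
    return result


def evaluate_batch(
    sites,
    climates: dict[str, MonthlyClimate],
    co2: Co2Table,
    params: LueParams = LueParams(),
    **kwargs,
) -> list[SiteResult]:
    """Evaluate many sites; sites without climate get an all-missing one."""
    import numpy as np

    results = []
    for site in sites:
        climate = climates.get(site.site_id)
        if climate is None:
            climate = MonthlyClimate(
                temp=np.full(12, math.nan), srad=np.full(12, math.nan)
            )
        results.append(evaluate_site(site, climate, co2, params, **kwargs))
    return results
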